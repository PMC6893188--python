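"""End-to-end study drivers on synthetic data.

Each function runs one stage of the full study at a reproducible,
desk-scale problem size and returns a dict of computed quantities:

- :func:`segmentation_benchmark` — train the 5-member U-net ensemble on
  small synthetic epidermis tiles and score pixel F1 and trait
  accuracies on held-out images.
- :func:`heritability_study` — simulate the two-environment augmented
  incomplete-block trial for both bulliform traits, screen outliers,
  reduce the model, and estimate BLUPs plus plot- and line-mean-basis
  heritability.
- :func:`gwas_study` — null calibration, planted-QTL power, and the
  LD-window candidate-gene report.

The scaled-down segmentation benchmark uses 128 x 128 tiles with a
depth-2, 8-channel U-net: large enough that the ensemble must actually
learn texture-vs-column discrimination, small enough for a single CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import gwas as gw
from . import quantgen as qg
from . import segmentation as seg
from . import traits
from .candidates import candidate_genes, window_report
from .synth import (
    FieldDesign,
    GenotypeSimParams,
    ImageSimParams,
    VarianceComponents,
    gen_annotation_and_de,
    gen_epidermis_image,
    gen_field_phenotypes,
    gen_genotypes,
)
from .synth.genotypes import qtl_phenotype
from .unet import UNetConfig

BENCH_TILE = 128


def benchmark_image_params(seed: int, n_columns: int) -> ImageSimParams:
    """Study conditions of one scaled-down benchmark image."""
    return ImageSimParams(
        height_px=BENCH_TILE, width_px=BENCH_TILE, n_columns=n_columns,
        column_width_px=12.0, column_spacing_jitter=2.0, edge_jitter_px=1.5,
        background_cell_scale_px=6.0, seed=seed,
    )


def make_benchmark_set(n_images: int, seed: int):
    """Images, masks and truth records for the benchmark distribution
    (3-5 columns per 128 px image, ~12 px nominal width)."""
    rng = np.random.default_rng(seed)
    imgs, masks, truths = [], [], []
    for i in range(n_images):
        n_cols = int(rng.integers(3, 6))
        p = benchmark_image_params(seed=int(rng.integers(2**31)), n_columns=n_cols)
        im, mk, tr = gen_epidermis_image(p)
        imgs.append(im)
        masks.append(mk)
        truths.append(tr)
    return np.asarray(imgs, dtype=np.float32), np.asarray(masks), truths


def benchmark_config(seed: int, ensemble_size: int = 5, epochs: int = 10) -> UNetConfig:
    return UNetConfig(
        depth=2, base_channels=8, input_size=BENCH_TILE, learning_rate=1e-3,
        epochs=epochs, batch_size=4, ensemble_size=ensemble_size, seed=seed,
    )


def segmentation_benchmark(
    seed: int = 0,
    n_train: int = 96,
    n_test: int = 24,
    ensemble_size: int = 5,
    epochs: int = 10,
    return_members: bool = False,
) -> dict:
    """Scaled-down ensemble benchmark; returns F1 and trait accuracies."""
    train_imgs, train_masks, _ = make_benchmark_set(n_train, seed)
    test_imgs, test_masks, _ = make_benchmark_set(n_test, seed + 1)
    cfg = benchmark_config(seed, ensemble_size=ensemble_size, epochs=epochs)
    members, histories = seg.train_ensemble(train_imgs, train_masks, cfg)
    pred = seg.predict_ensemble(members, test_imgs)

    f1 = float(np.mean([seg.pixel_f1(p, t) for p, t in zip(pred, test_masks)]))
    pred_counts, man_counts, pred_widths, man_widths = {}, {}, {}, {}
    for i, (pm, tm) in enumerate(zip(pred, test_masks)):
        pred_counts[i] = traits.count_columns(pm)
        man_counts[i] = traits.count_columns(tm)
        man_widths[i] = traits.column_width(tm) if man_counts[i] else np.nan
        pred_widths[i] = traits.column_width(pm) if pred_counts[i] else 0.0
    count_acc = seg.evaluate_accuracy(pred_counts, man_counts)
    width_acc = seg.evaluate_accuracy(pred_widths, man_widths)
    out = {
        "pixel_f1": f1,
        "column_number_accuracy_pct": count_acc["accuracy_pct"],
        "column_width_accuracy_pct": width_acc["accuracy_pct"],
        "n_train": n_train,
        "n_test": n_test,
        "final_train_loss": histories[0]["train_loss"][-1],
        "val_losses": [h["val_loss"][-1] for h in histories if h["val_loss"]],
    }
    if return_members:
        out["members"] = members
        out["histories"] = histories
    return out


#: Variance components chosen to mirror the trait regime of the emulated
#: maize panel: line-mean
#: h2 ~ 0.76 for column number, ~ 0.71 for column width.
TRAIT_COMPONENTS = {
    "column_number": VarianceComponents(
        sigma2_G=0.50, sigma2_GE=0.10, sigma2_env=0.30,
        sigma2_block=0.05, sigma2_col=0.05, sigma2_eps=0.20,
    ),
    "column_width_um": VarianceComponents(
        sigma2_G=104.0, sigma2_GE=18.0, sigma2_env=30.0,
        sigma2_block=8.0, sigma2_col=8.0, sigma2_eps=48.0,
    ),
}
TRAIT_MEANS = {"column_number": 9.35, "column_width_um": 103.51}


def true_line_mean_h2(vc: VarianceComponents, n_env: int = 2, n_rep: int = 1) -> float:
    return vc.sigma2_G / (
        vc.sigma2_G + vc.sigma2_GE / n_env + vc.sigma2_eps / (n_env * n_rep)
    )


def heritability_study(
    seed: int = 0,
    n_keep_lines: int = 461,
    design: FieldDesign | None = None,
    traits_spec: dict | None = None,
) -> dict:
    """Simulate and analyse both bulliform traits at panel scale.

    468 lines are planted; a random subset is retained (default 461,
    emulating QC attrition), then per trait: outlier screening on the
    full model, backward model reduction, BLUPs, plot-basis (per
    environment) and line-mean-basis heritability with delta-method SEs,
    and the cross-environment Pearson correlation of per-environment
    line BLUPs.
    """
    design = design or FieldDesign(seed=seed)
    traits_spec = traits_spec or TRAIT_COMPONENTS
    rng = np.random.default_rng(seed + 17)
    out: dict = {}
    for t_i, (trait, vc) in enumerate(traits_spec.items()):
        pheno, truth = gen_field_phenotypes(
            design, vc, seed=seed + 1000 * t_i,
            grand_mean=TRAIT_MEANS.get(trait, 10.0),
            check_effects={"N28HT": 0.5, "Mo17": -0.5},
            trait="trait",
        )
        lines = sorted(pheno.loc[~pheno.is_check, "entry"].unique())
        keep = set(rng.choice(lines, size=min(n_keep_lines, len(lines)), replace=False))
        pheno = pheno[pheno.is_check | pheno.entry.isin(keep)].reset_index(drop=True)

        spec = qg.ModelSpec(trait="trait")
        cleaned, flags = qg.screen_outliers(pheno, spec)
        final_fit, history = qg.reduce_model(cleaned, spec)
        h2_lm = qg.heritability(final_fit, "line-mean")
        blups = final_fit.line_blups() + float(final_fit.beta[0])

        env_results = {}
        for env in design.environments:
            env_spec = qg.single_env_spec(env, trait="trait")
            env_clean, _ = qg.screen_outliers(pheno, env_spec)
            env_fit = qg.fit_reml(env_clean, env_spec)
            h2_plot = qg.heritability(env_fit, "plot")
            env_results[env] = {
                "h2_plot": h2_plot.estimate, "h2_plot_se": h2_plot.se,
                "blups": env_fit.line_blups() + float(env_fit.beta[0]),
            }
        e1, e2 = design.environments
        common = env_results[e1]["blups"].index.intersection(env_results[e2]["blups"].index)
        r_env = float(stats.pearsonr(
            env_results[e1]["blups"][common], env_results[e2]["blups"][common]
        )[0])

        out[trait] = {
            "true_h2_line_mean": true_line_mean_h2(vc),
            "h2_line_mean": h2_lm.estimate,
            "h2_line_mean_se": h2_lm.se,
            "h2_plot_by_env": {e: env_results[e]["h2_plot"] for e in env_results},
            "blup_mean": float(blups.mean()),
            "blup_sd": float(blups.std()),
            "cross_env_blup_corr": r_env,
            "n_outliers_removed": int(flags["outlier"].sum()),
            "final_random_terms": list(final_fit.spec.random_terms),
            "varcomp": final_fit.varcomp,
            "n_lines": int(len(blups)),
        }
    return out


def h2_recovery(seed: int = 0, n_keep_lines: int = 461) -> dict:
    """Line-mean heritability recovery at panel scale for both traits.

    Simulates the two-environment trial, fits the full mixed model by
    REML, and compares the line-mean-basis estimate against the
    components' true value.
    """
    design = FieldDesign(seed=seed)
    rng = np.random.default_rng(seed + 17)
    out = {}
    for t_i, (trait, vc) in enumerate(TRAIT_COMPONENTS.items()):
        pheno, _ = gen_field_phenotypes(
            design, vc, seed=seed + 1000 * t_i,
            grand_mean=TRAIT_MEANS.get(trait, 10.0),
            check_effects={"N28HT": 0.5, "Mo17": -0.5},
        )
        lines = sorted(pheno.loc[~pheno.is_check, "entry"].unique())
        keep = set(rng.choice(lines, size=min(n_keep_lines, len(lines)), replace=False))
        pheno = pheno[pheno.is_check | pheno.entry.isin(keep)].reset_index(drop=True)
        fit = qg.fit_reml(pheno, qg.ModelSpec())
        est = qg.heritability(fit, "line-mean")
        truth = true_line_mean_h2(vc)
        out[trait] = {
            "h2_true": truth,
            "h2_estimate": est.estimate,
            "h2_se": est.se,
            "abs_error": abs(est.estimate - truth),
            "n_lines": len(keep),
        }
    return out


def null_calibration(seed: int = 0, n_reps: int = 3, n_snps: int = 2000) -> dict:
    """Type-I error of the P3D scan under structured polygenic nulls.

    Pools p-values from ``n_reps`` independent null panels (200 inbred
    lines each, polygenic trait drawn from the panel's own kinship, no
    QTL).  The error rate and KS uniformity check are evaluated on each
    panel's LD-pruned (r^2 <= 0.2) SNP subset, where tests are close to
    independent and the binomial reference interval is appropriate;
    pooling replicates averages out LD clustering within a panel.
    """
    pooled = []
    for rep in range(n_reps):
        gp0 = GenotypeSimParams(n_lines=200, n_snps=n_snps, ld_block_len=40,
                                n_founders=6, seed=seed + 50 + 1000 * rep)
        dos0, info0, _ = gen_genotypes(gp0)
        pruned = gw.ld_prune(dos0, info0)
        K0 = gw.kinship_vanraden(dos0[:, pruned])
        rng = np.random.default_rng(seed + 51 + 1000 * rep)
        L = np.linalg.cholesky(K0 + 1e-6 * np.eye(200))
        y0 = L @ rng.normal(size=200) + rng.normal(size=200)
        res0 = gw.gwas_p3d(y0, dos0, info0, K0)
        pooled.append(res0["p"].iloc[pruned].dropna().to_numpy())
    p = np.concatenate(pooled)
    lo, hi = stats.binom.interval(0.95, len(p), 0.05)
    return {
        "type1_error_rate": float((p < 0.05).mean()),
        "binom_ci": (lo / len(p), hi / len(p)),
        "ks_uniform_p": float(stats.kstest(p, "uniform").pvalue),
        "n_pvalues": int(len(p)),
    }


def gwas_study(
    seed: int = 0,
    n_lines: int = 400,
    n_snps: int = 2000,
    n_power_reps: int = 20,
    qtl_effect: float = 0.5,
) -> dict:
    """GWAS calibration, power and candidate-window extraction.

    Null calibration: a structured polygenic phenotype (no QTL) on 200
    lines x ``n_snps`` SNPs; empirical type-I error at alpha = 0.05 and
    a KS test of p-value uniformity.  Power: ``n_power_reps`` seeded
    replicates with one planted QTL; a hit is the minimum-p SNP being
    the causal SNP or an r^2 > 0.8 proxy.  Finally one replicate is
    carried through covariate selection, the scan, BH-FDR and the
    r^2 > 0.5 candidate window cross-referenced against a synthetic DE
    table.
    """
    # --- null calibration ---------------------------------------------
    calib = null_calibration(seed=seed, n_snps=n_snps)
    rng = np.random.default_rng(seed + 51)

    # --- power --------------------------------------------------------
    hits = 0
    for rep in range(n_power_reps):
        gp = GenotypeSimParams(
            n_lines=n_lines, n_snps=1000, ld_block_len=25,
            seed=seed + 100 + rep, causal=[(500, qtl_effect)],
        )
        dos, info, _ = gen_genotypes(gp)
        y = qtl_phenotype(dos, gp.causal, noise_sd=1.0, seed=seed + 200 + rep)
        K = gw.kinship_vanraden(dos[:, gw.ld_prune(dos, info)])
        res = gw.gwas_p3d(y, dos, info, K)
        top = int(res["p"].idxmin())
        hits += (top == 500) or (gw.ld_r2(dos[:, top], dos[:, 500]) > 0.8)
    power = hits / n_power_reps

    # --- one full scan with covariates and candidate window ------------
    gp = GenotypeSimParams(
        n_lines=n_lines, n_snps=1000, ld_block_len=80, n_founders=8,
        founder_corr=0.98, recomb_rate=0.01, mutation_rate=0.005,
        missing_rate=0.05, het_rate=0.01,
        seed=seed + 300, causal=[(500, qtl_effect)],
    )
    dos, info, _ = gen_genotypes(gp)
    kept, snp_qc = gw.filter_snps(dos)
    dos_f, info_f = dos[:, kept], info.iloc[kept].reset_index(drop=True)
    causal_f = int(np.flatnonzero(kept == 500)[0]) if 500 in kept else None
    y = qtl_phenotype(dos, gp.causal, noise_sd=1.0, seed=seed + 301)
    ft = rng.normal(size=n_lines)
    K = gw.kinship_vanraden(dos_f[:, gw.ld_prune(dos_f, info_f)])
    pcs = gw.genotype_pcs(dos_f, 10)
    chosen, bic_table = gw.select_covariates(y, ft, pcs, K)
    cov = []
    if chosen["flowering_time"]:
        cov.append(ft)
    if chosen["n_pcs"]:
        cov.append(pcs[:, : chosen["n_pcs"]])
    covariates = np.column_stack(cov) if cov else None
    res = gw.gwas_p3d(y, dos_f, info_f, K, covariates=covariates)

    chrom_len = int(info_f["pos"].max()) + 10_000
    genes, de = gen_annotation_and_de(
        {1: chrom_len}, n_genes=300, frac_up=0.2, frac_down=0.2, seed=seed + 302
    )
    win = candidate_genes(res, dos_f, info_f, genes, de)

    return {
        "type1_error_rate": calib["type1_error_rate"],
        "ks_uniform_p": calib["ks_uniform_p"],
        "n_null_snps": calib["n_pvalues"],
        "power": power,
        "n_power_reps": n_power_reps,
        "snps_kept_frac": float(len(kept) / dos.shape[1]),
        "covariates_chosen": chosen,
        "n_significant_fdr05": int(res["significant"].sum()),
        "min_p": float(res["p"].min()),
        "causal_kept": causal_f is not None,
        "window": window_report(win),
        "scan": res,
        "bic_table": bic_table,
    }
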