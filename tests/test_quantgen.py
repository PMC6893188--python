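"""Mixed models: REML correctness, model reduction, outliers, heritability."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from bulliform import quantgen as qg
from bulliform.synth import FieldDesign, VarianceComponents, gen_field_phenotypes


def anova_one_way(df, g, r):
    ybar = df.groupby("entry").trait.mean()
    grand = df.trait.mean()
    msb = r * ((ybar - grand) ** 2).sum() / (g - 1)
    msw = ((df.trait - df.entry.map(ybar)) ** 2).sum() / (g * (r - 1))
    return (msb - msw) / r, msw


def test_reml_equals_anova_on_balanced_one_way(one_way_balanced):
    """On balanced one-way data REML must match the MS-based closed form."""
    df, g, r = one_way_balanced
    fit = qg.fit_reml(df, qg.ModelSpec(random_terms=("genotype",)))
    s2g, s2e = anova_one_way(df, g, r)
    assert fit.varcomp["genotype"] == pytest.approx(s2g, abs=1e-6)
    assert fit.varcomp["residual"] == pytest.approx(s2e, abs=1e-6)


def test_loglik_nondecreasing(one_way_balanced):
    df, _, _ = one_way_balanced
    fit = qg.fit_reml(df, qg.ModelSpec(random_terms=("genotype",)))
    ll = np.array(fit.ll_path)
    assert np.all(np.diff(ll) >= -1e-8)


def test_all_equal_responses_give_zero_components(one_way_balanced):
    df, _, _ = one_way_balanced
    df = df.assign(trait=7.0)
    fit = qg.fit_reml(df, qg.ModelSpec(random_terms=("genotype",)))
    assert fit.varcomp["genotype"] == 0.0
    assert fit.varcomp["residual"] == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.line_blups().to_numpy(), 0.0)


def test_parameter_recovery_single_replicate_identified_functions(both_env_pheno):
    """On the single-replicate field layout G x E and residual variance are
    confounded (only their sum is identified); genotype variance and the
    G x E + residual sum must still be recovered."""
    pheno, vc, _ = both_env_pheno
    fit = qg.fit_reml(pheno, qg.ModelSpec())
    assert fit.varcomp["genotype"] == pytest.approx(vc.sigma2_G, abs=0.45)
    assert fit.varcomp["gxe"] + fit.varcomp["residual"] == pytest.approx(
        vc.sigma2_GE + vc.sigma2_eps, abs=0.5
    )


def test_parameter_recovery_replicated_design():
    """With 2 plots per line and environment every component is identified:
    estimates land within 3 SE of the simulated truth (200 lines)."""
    from conftest import make_replicated_pheno

    vc = VarianceComponents(1.0, 0.5, 0.2, 0.2, 0.2, 1.0)
    pheno = make_replicated_pheno(vc, seed=21, n_lines=200, n_reps=2)
    fit = qg.fit_reml(pheno, qg.ModelSpec())
    order = fit.varcomp_order
    se = np.sqrt(np.diag(fit.varcomp_cov))
    for term, truth in [("genotype", 1.0), ("gxe", 0.5), ("residual", 1.0)]:
        i = order.index(term)
        assert abs(fit.varcomp[term] - truth) < 3 * se[i] + 0.05, (term, fit.varcomp)


def test_results_invariant_to_row_order(both_env_pheno):
    pheno, _, _ = both_env_pheno
    fit1 = qg.fit_reml(pheno, qg.ModelSpec())
    shuffled = pheno.sample(frac=1.0, random_state=3).reset_index(drop=True)
    fit2 = qg.fit_reml(shuffled, qg.ModelSpec())
    for k in fit1.varcomp:
        assert fit1.varcomp[k] == pytest.approx(fit2.varcomp[k], rel=1e-4, abs=1e-8)
    pd.testing.assert_series_equal(
        fit1.line_blups().sort_index(), fit2.line_blups().sort_index(),
        rtol=1e-4, atol=1e-8,
    )


def test_blup_shrinkage(both_env_pheno):
    """BLUP variance never exceeds the raw line-mean variance."""
    pheno, _, _ = both_env_pheno
    fit = qg.fit_reml(pheno, qg.ModelSpec())
    raw = pheno[~pheno.is_check].groupby("entry")["trait"].mean()
    blups = fit.line_blups()
    assert blups.var() < raw.var()


def test_reml_matches_lme4_cross_check(tmp_path):
    """Independent oracle: lme4 REML on a replicated two-environment design
    (all components identified, so both optimizers must agree)."""
    from conftest import make_replicated_pheno

    vc = VarianceComponents(1.0, 0.5, 0.3, 0.2, 0.2, 1.0)
    pheno = make_replicated_pheno(vc, seed=31, n_lines=60, n_reps=2)
    fit = qg.fit_reml(pheno, qg.ModelSpec())
    csv = tmp_path / "pheno.csv"
    pheno.assign(
        ge=pheno.entry + ":" + pheno.env,
        blk=pheno.env + ":" + pheno.block,
        cl=pheno.env + ":" + pheno.col,
    ).to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    out = tmp_path / "vc.csv"
    rscript.write_text(textwrap.dedent("""
        suppressMessages(library(lme4))
        args <- commandArgs(TRUE)
        d <- read.csv(args[1])
        m <- lmer(trait ~ 1 + (1|env) + (1|entry) + (1|ge) + (1|blk) + (1|cl),
                  data = d, REML = TRUE)
        v <- as.data.frame(VarCorr(m))
        write.csv(v[, c("grp", "vcov")], args[2], row.names = FALSE)
    """))
    res = subprocess.run(
        ["Rscript", str(rscript), str(csv), str(out)],
        capture_output=True, text=True, timeout=300,
    )
    assert res.returncode == 0, res.stderr
    vc_r = pd.read_csv(out).set_index("grp")["vcov"]
    mapping = {"entry": "genotype", "ge": "gxe", "blk": "block", "cl": "col",
               "env": "env", "Residual": "residual"}
    for r_name, ours in mapping.items():
        assert fit.varcomp[ours] == pytest.approx(vc_r[r_name], rel=0.02, abs=0.02), ours


def test_model_reduction_drops_null_block_and_keeps_gxe():
    """block(env) simulated at zero variance is eliminated; a strong G x E
    term survives (majority over seeded replicates; replicated design so
    G x E is identified against residual)."""
    from conftest import make_replicated_pheno

    vc = VarianceComponents(
        sigma2_G=1.0, sigma2_GE=1.0, sigma2_env=0.3,
        sigma2_block=0.0, sigma2_col=0.3, sigma2_eps=0.5,
    )
    dropped_block, kept_gxe = 0, 0
    reps = 5
    for seed in range(reps):
        pheno = make_replicated_pheno(vc, seed=100 + seed, n_lines=60, n_reps=2)
        fit, _ = qg.reduce_model(pheno, qg.ModelSpec())
        dropped_block += "block" not in fit.spec.random_terms
        kept_gxe += "gxe" in fit.spec.random_terms
    assert dropped_block >= reps - 1
    assert kept_gxe == reps


def test_full_model_retained_when_all_terms_strong():
    """All multi-level terms strongly supported survive reduction.  (The
    2-level environment term is statistically untestable with one degree
    of freedom and is allowed to go either way.)"""
    from conftest import make_replicated_pheno

    vc = VarianceComponents(1.0, 1.0, 1.0, 1.0, 1.0, 0.5)
    pheno = make_replicated_pheno(vc, seed=1, n_lines=60, n_reps=2)
    fit, history = qg.reduce_model(pheno, qg.ModelSpec())
    assert {"genotype", "gxe", "block", "col"} <= set(fit.spec.random_terms)


def test_outlier_screen_calibration_and_planted(small_design):
    vc = VarianceComponents(0.5, 0.2, 0.2, 0.1, 0.1, 0.5)
    pheno, _ = gen_field_phenotypes(small_design, vc, seed=4)
    n = len(pheno)
    # plant one gross outlier: +10 residual SD
    pheno = pheno.copy()
    pheno.loc[17, "trait"] += 10 * np.sqrt(vc.sigma2_eps)
    cleaned, flags = qg.screen_outliers(pheno, qg.ModelSpec(), alpha=0.05)
    assert bool(flags.loc[17, "outlier"])
    # clean-data false-positive rate ~ alpha
    frac = flags["outlier"].mean()
    assert 0.01 < frac < 0.12
    # alpha = 0 removes nothing
    cleaned0, flags0 = qg.screen_outliers(pheno, qg.ModelSpec(), alpha=0.0)
    assert flags0["outlier"].sum() == 0 and len(cleaned0) == n


def test_heritability_formula_arithmetic():
    """Closed-form check: s2G=1, s2GE=.5, s2e=1, 2 envs, 1 rep ->
    line-mean h2 = 1 / (1 + .25 + .5)."""
    design = FieldDesign(n_blocks=3, seed=0)
    vc = VarianceComponents(1.0, 0.5, 0.1, 0.0, 0.0, 1.0)
    pheno, _ = gen_field_phenotypes(design, vc, seed=0)
    fit = qg.fit_reml(pheno, qg.ModelSpec())
    # overwrite estimates with exact values to isolate the formula
    fit.varcomp.update(genotype=1.0, gxe=0.5, residual=1.0)
    h2 = qg.heritability(fit, "line-mean")
    assert h2.estimate == pytest.approx(1 / 1.75)
    assert h2.detail["n_E"] == pytest.approx(2.0)
    # degenerate case: no G x E and no residual noise -> h2 = 1
    fit.varcomp.update(gxe=0.0, residual=0.0)
    assert qg.heritability(fit, "line-mean").estimate == pytest.approx(1.0)


def test_plot_basis_heritability(one_way_balanced):
    df, g, r = one_way_balanced
    fit = qg.fit_reml(df, qg.ModelSpec(random_terms=("genotype",)))
    h2 = qg.heritability(fit, "plot")
    s2g, s2e = anova_one_way(df, g, r)
    assert h2.estimate == pytest.approx(s2g / (s2g + s2e), abs=1e-6)
    assert 0 < h2.se < 0.2


def test_delta_se_close_to_parametric_bootstrap(small_design):
    """Delta-method SE of line-mean h2 agrees with a parametric bootstrap
    on a mid-size simulation (tolerance covers bootstrap noise at B=40)."""
    vc = VarianceComponents(1.0, 0.3, 0.2, 0.1, 0.1, 1.0)
    pheno, _ = gen_field_phenotypes(small_design, vc, seed=2)
    fit = qg.fit_reml(pheno, qg.ModelSpec())
    delta_se = qg.heritability(fit, "line-mean").se
    est_vc = VarianceComponents(
        sigma2_G=fit.varcomp["genotype"], sigma2_GE=fit.varcomp["gxe"],
        sigma2_env=fit.varcomp["env"], sigma2_block=fit.varcomp["block"],
        sigma2_col=fit.varcomp["col"], sigma2_eps=fit.varcomp["residual"],
    )
    boots = []
    for b in range(40):
        sim, _ = gen_field_phenotypes(small_design, est_vc, seed=500 + b)
        bfit = qg.fit_reml(sim, qg.ModelSpec())
        boots.append(qg.heritability(bfit, "line-mean").estimate)
    boot_se = float(np.std(boots, ddof=1))
    assert delta_se == pytest.approx(boot_se, rel=0.25)


def test_spec_validation():
    with pytest.raises(ValueError, match="G x E"):
        qg.ModelSpec(random_terms=("genotype", "gxe"), scope="AZ")
    with pytest.raises(ValueError, match="unknown"):
        qg.ModelSpec(random_terms=("genotype", "year"))
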