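"""SNP QC, LD, kinship, covariate selection, P3D scan, FDR, windows."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from bulliform import gwas as gw
from bulliform.candidates import candidate_genes, window_report
from bulliform.synth import GenotypeSimParams, gen_annotation_and_de, gen_genotypes
from bulliform.synth.genotypes import MISSING, qtl_phenotype


# ---------------------------------------------------------------- filters
class TestSnpFilters:
    def make_panel(self):
        """Hand-built panel with known per-SNP statistics (200 lines)."""
        n = 200
        dos = np.zeros((n, 5), dtype=np.int8)
        dos[:20, 0] = 2              # MAC 40 exactly -> kept
        dos[:19, 1] = 2              # MAC 38 -> dropped (mac)
        dos[:50, 2] = 2
        dos[120:, 2] = MISSING       # call rate 0.6 exactly -> kept
        dos[:30, 3] = 1
        dos[30:60, 3] = 2            # het 15% -> dropped (het)
        dos[:60, 4] = 2              # clean -> kept
        return dos

    def test_boundary_cases(self):
        kept, st_ = gw.filter_snps(self.make_panel())
        assert 0 in kept and 4 in kept
        assert st_.loc[1, "drop_reason"] == "mac"
        assert 2 in kept and st_.loc[2, "call_rate"] == pytest.approx(0.6)
        assert st_.loc[3, "drop_reason"] == "het"

    def test_call_rate_below_threshold_dropped(self):
        dos = self.make_panel()
        dos[118:, 2] = MISSING  # call rate 0.59
        kept, st_ = gw.filter_snps(dos)
        assert st_.loc[2, "drop_reason"] == "call_rate"

    def test_monomorphic_dropped_with_reason(self):
        dos = np.zeros((100, 1), dtype=np.int8)
        kept, st_ = gw.filter_snps(dos)
        assert len(kept) == 0 and st_.loc[0, "drop_reason"] == "monomorphic"

    def test_matches_brute_force_oracle(self, small_panel):
        dos, info, _ = small_panel
        cfg = gw.SnpFilterConfig(min_mac=30, min_call_rate=0.9, max_het=0.05,
                                 min_inbreeding=0.8)
        kept, _ = gw.filter_snps(dos, cfg)
        expected = []
        for j in range(dos.shape[1]):
            col = dos[:, j].astype(float)
            col[dos[:, j] == MISSING] = np.nan
            called = col[~np.isnan(col)]
            if len(called) == 0:
                continue
            alt = called.sum()
            mac = min(alt, 2 * len(called) - alt)
            p = alt / (2 * len(called))
            if p in (0.0, 1.0):
                continue
            het = (called == 1).mean()
            F = 1 - het / (2 * p * (1 - p))
            if (mac >= 30 and len(called) / dos.shape[0] >= 0.9
                    and het <= 0.05 and F >= 0.8):
                expected.append(j)
        assert list(kept) == expected


# ---------------------------------------------------------------- LD
class TestLD:
    def test_r2_self_is_one(self, small_panel):
        dos, _, _ = small_panel
        assert gw.ld_r2(dos[:, 0], dos[:, 0]) == pytest.approx(1.0)

    def test_r2_invariant_to_allele_flip(self, small_panel):
        dos, _, _ = small_panel
        flipped = 2 - dos[:, 0]
        assert gw.ld_r2(dos[:, 0], flipped) == pytest.approx(1.0)

    def test_r2_symmetric_and_bounded(self, small_panel):
        dos, _, _ = small_panel
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.integers(0, dos.shape[1], 2)
            a = gw.ld_r2(dos[:, i], dos[:, j])
            b = gw.ld_r2(dos[:, j], dos[:, i])
            if np.isfinite(a):
                assert a == pytest.approx(b)
                assert 0.0 <= a <= 1.0

    def test_r2_undefined_for_constant_snp(self):
        assert np.isnan(gw.ld_r2(np.zeros(50), np.arange(50) % 3))

    def test_null_mean_r2_near_one_over_n(self):
        params = GenotypeSimParams(n_lines=400, n_snps=200, ld_block_len=1, seed=8)
        dos, _, _ = gen_genotypes(params)
        vals = [gw.ld_r2(dos[:, j], dos[:, j + 1]) for j in range(199)]
        assert np.nanmean(vals) == pytest.approx(1 / 400, abs=3 / 400)


class TestLDPrune:
    def test_independent_snps_all_retained(self):
        params = GenotypeSimParams(n_lines=500, n_snps=60, ld_block_len=1, seed=9)
        dos, info, _ = gen_genotypes(params)
        kept = gw.ld_prune(dos, info, r2_max=0.2)
        assert len(kept) >= 55  # only chance pairs above threshold removed

    def test_duplicated_snp_removed(self, small_panel):
        dos, info, _ = small_panel
        dup = np.column_stack([dos[:, :10], dos[:, 5]])
        info2 = pd.concat(
            [info.iloc[:10], info.iloc[[5]].assign(pos=info.pos.iloc[9] + 1)],
            ignore_index=True,
        )
        kept = gw.ld_prune(dup, info2, r2_max=0.2)
        assert not (5 in kept and 10 in kept)

    def test_retained_pairs_below_threshold_brute_force(self, small_panel):
        dos, info, _ = small_panel
        kept = gw.ld_prune(dos, info, r2_max=0.2, window=50, step=5)
        d = gw.mean_impute(dos)[:, kept]
        # audit retained pairs guaranteed to have shared a window: with
        # window 50 and step 5, any pair closer than window - step in the
        # original index space was examined together at least once
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if kept[b] - kept[a] > 45:
                    break
                if d[:, a].std() == 0 or d[:, b].std() == 0:
                    continue
                r = np.corrcoef(d[:, a], d[:, b])[0, 1] ** 2
                assert r <= 0.2 + 1e-9


# ---------------------------------------------------------------- kinship
class TestKinship:
    def test_identical_inbred_lines_identity_by_state(self):
        rng = np.random.default_rng(1)
        base = (rng.random(300) < 0.3).astype(np.int8) * 2
        dos = np.vstack([base, base, 2 - base])
        K = gw.kinship_vanraden(dos)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K.shape == (3, 3)
        assert np.allclose(K, K.T)

    def test_diagonal_close_to_one_plus_inbreeding(self, small_panel):
        dos, _, _ = small_panel
        K = gw.kinship_vanraden(dos)
        # fully inbred panel: F ~ 1, mean diagonal ~ 2 under VanRaden with
        # HWE-expected scaling; at least well above the outbred value 1
        assert 1.5 < np.mean(np.diag(K)) < 2.5

    def test_psd(self, small_panel):
        dos, _, _ = small_panel
        K = gw.kinship_vanraden(dos)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-8

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gw.kinship_vanraden(np.zeros((10, 5)))


# ---------------------------------------------------------------- BH FDR
class TestBH:
    def test_worked_example(self):
        q = gw.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert gw.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_empty(self):
        assert gw.bh_fdr([]).size == 0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    def test_matches_statsmodels_step_up(self, pvals):
        ours = gw.bh_fdr(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            gw.bh_fdr([0.0, 0.5])


# ---------------------------------------------------------------- P3D scan
class TestP3D:
    def test_identity_kinship_equals_ols(self, small_panel):
        dos, info, _ = small_panel
        n = dos.shape[0]
        rng = np.random.default_rng(3)
        y = rng.normal(size=n)
        res = gw.gwas_p3d(y, dos, info, np.eye(n))
        d = gw.mean_impute(dos)
        for j in range(0, dos.shape[1], 61):
            X = sm.add_constant(d[:, j])
            if np.linalg.matrix_rank(X) < 2:
                continue
            ols = sm.OLS(y, X).fit()
            assert res.loc[j, "p"] == pytest.approx(ols.pvalues[1], abs=1e-8)
            assert res.loc[j, "effect"] == pytest.approx(ols.params[1], abs=1e-8)

    def test_scan_invariant_to_snp_order_and_recoding(self, small_panel):
        dos, info, _ = small_panel
        rng = np.random.default_rng(4)
        y = rng.normal(size=dos.shape[0])
        K = gw.kinship_vanraden(dos)
        res = gw.gwas_p3d(y, dos, info, K)
        perm = rng.permutation(dos.shape[1])
        res_perm = gw.gwas_p3d(y, dos[:, perm], info.iloc[perm].reset_index(drop=True), K)
        assert np.allclose(res_perm["p"].to_numpy(), res["p"].to_numpy()[perm], equal_nan=True)
        flipped = np.where(dos == MISSING, MISSING, 2 - dos).astype(np.int8)
        res_flip = gw.gwas_p3d(y, flipped, info, K)
        assert np.allclose(res_flip["p"], res["p"], equal_nan=True)

    def test_planted_qtl_detected(self):
        hits = 0
        for rep in range(6):
            gp = GenotypeSimParams(n_lines=400, n_snps=600, ld_block_len=25,
                                   seed=700 + rep, causal=[(300, 0.5)])
            dos, info, _ = gen_genotypes(gp)
            y = qtl_phenotype(dos, gp.causal, noise_sd=1.0, seed=rep)
            K = gw.kinship_vanraden(dos[:, gw.ld_prune(dos, info)])
            res = gw.gwas_p3d(y, dos, info, K)
            top = int(res["p"].idxmin())
            hits += (top == 300) or (gw.ld_r2(dos[:, top], dos[:, 300]) > 0.8)
        assert hits >= 5

    def test_constant_snp_skipped(self, small_panel):
        dos, info, _ = small_panel
        dos = dos.copy()
        dos[:, 7] = 2
        rng = np.random.default_rng(5)
        res = gw.gwas_p3d(rng.normal(size=dos.shape[0]), dos, info, np.eye(dos.shape[0]))
        assert np.isnan(res.loc[7, "p"])

    def test_misaligned_inputs_rejected(self, small_panel):
        dos, info, _ = small_panel
        with pytest.raises(ValueError, match="misaligned"):
            gw.gwas_p3d(np.zeros(10), dos, info, np.eye(dos.shape[0]))


# ---------------------------------------------------- covariate selection
class TestCovariateSelection:
    def test_flowering_time_signal_selected(self, small_panel):
        dos, info, _ = small_panel
        n = dos.shape[0]
        rng = np.random.default_rng(6)
        ft = rng.normal(size=n)
        y = 0.8 * ft + 0.5 * rng.normal(size=n)
        K = gw.kinship_vanraden(dos)
        pcs = gw.genotype_pcs(dos, 10)
        chosen, table = gw.select_covariates(y, ft, pcs, K)
        assert chosen == {"flowering_time": True, "n_pcs": 0}

    def test_independent_trait_selects_nothing(self, small_panel):
        dos, info, _ = small_panel
        rng = np.random.default_rng(7)
        y = rng.normal(size=dos.shape[0])
        chosen, _ = gw.select_covariates(
            y, rng.normal(size=dos.shape[0]), gw.genotype_pcs(dos, 10),
            gw.kinship_vanraden(dos),
        )
        assert chosen == {"flowering_time": False, "n_pcs": 0}

    def test_bic_penalty_rejects_noise_candidate(self, small_panel):
        dos, _, _ = small_panel
        rng = np.random.default_rng(8)
        n = dos.shape[0]
        y = rng.normal(size=n)
        chosen, table = gw.select_covariates(
            y, rng.normal(size=n), None, gw.kinship_vanraden(dos), max_pcs=0
        )
        assert chosen["flowering_time"] is False


# ---------------------------------------------------------------- windows
class TestCandidateWindows:
    def build_fixture(self):
        """A constructed locus: 9 genes inside the r^2>0.5 span, 1 up."""
        rng = np.random.default_rng(10)
        n = 300
        core = (rng.random(n) < 0.4).astype(np.int8) * 2
        cols, pos = [], []
        # 6 high-LD proxies of the core SNP spanning 90 kb, then decayed SNPs
        for k in range(7):
            noisy = core.copy()
            flip = rng.random(n) < (0.02 * k)
            noisy[flip] = 2 - noisy[flip]
            cols.append(noisy)
            pos.append(10_000 + 15_000 * k)
        for k in range(10):
            cols.append((rng.random(n) < 0.3).astype(np.int8) * 2)
            pos.append(200_000 + 10_000 * k)
        dos = np.column_stack(cols)
        info = pd.DataFrame(
            {"snp_id": [f"S{j}" for j in range(dos.shape[1])],
             "chrom": 4, "pos": pos}
        )
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{k}" for k in range(12)],
                "chrom": 4,
                "start": [12_000 + 9_000 * k for k in range(12)],
                "end": [12_000 + 9_000 * k + 4_000 for k in range(12)],
                "strand": "+",
            }
        )
        # genes 0..9 start within [10000, 100000]; gene at 12000+9000*9=93000
        # window should cover pos 10000..100000 given strong LD proxies
        de = pd.DataFrame(
            {
                "gene_id": genes.gene_id,
                "logFC": [2.0] + [-1.5] * 3 + [0.05] * 8,
                "FDR": [0.01] + [0.05] * 3 + [0.5] * 8,
            }
        )
        result = pd.DataFrame({"p": np.linspace(0.5, 0.9, dos.shape[1])})
        result.loc[0, "p"] = 1e-8  # S0 (the core) is the top SNP
        return dos, info, genes, de, result

    def test_window_with_nine_genes_one_upregulated(self):
        dos, info, genes, de, result = self.build_fixture()
        win = candidate_genes(result, dos, info, genes, de)
        rep = window_report(win)
        assert win.top_snp == "S0"
        assert win.start == 10_000 and win.end == 100_000
        assert rep["n_genes"] == 10  # genes overlapping [10k, 100k]
        assert rep["n_upregulated"] == 1
        assert rep["n_downregulated"] == 3

    def test_no_partner_degenerates_to_point(self):
        dos, info, genes, de, result = self.build_fixture()
        solo = dos.copy()
        rng = np.random.default_rng(11)
        for j in range(1, solo.shape[1]):
            solo[:, j] = (rng.random(300) < 0.3).astype(np.int8) * 2
        win = candidate_genes(result, solo, info, genes, de)
        assert win.degenerate
        assert win.start == win.end == info.loc[0, "pos"]
        # only genes overlapping the single position remain
        assert all(
            (g.start <= win.top_pos <= g.end) for g in win.genes.itertuples()
        )

    def test_gene_outside_window_excluded(self):
        dos, info, genes, de, result = self.build_fixture()
        win = candidate_genes(result, dos, info, genes, de)
        outside = genes[(genes.end < win.start) | (genes.start > win.end)]
        assert not set(outside.gene_id) & set(win.genes.gene_id)
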