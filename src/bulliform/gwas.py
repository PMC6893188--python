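"""P3D mixed-model GWAS with SNP QC, kinship, covariate selection and FDR.

The association model for line BLUPs y is

    y = X beta + s alpha + u + e,   u ~ N(0, s2_g K),  e ~ N(0, s2_e I)

with K the VanRaden genomic relationship matrix from LD-pruned markers.
Under P3D ("population parameters previously determined") the two
variance components are estimated once by REML under the null model
(no SNP) via the spectral decomposition of K, then fixed for every SNP
test; each SNP is tested with a generalized-least-squares Wald t-test
after whitening.  Multiple testing is controlled with Benjamini-
Hochberg q-values.

SNP quality filters mirror a GBS diversity panel: minimum minor-allele
count 40, call rate >= 60%, heterozygosity <= 10%, per-SNP inbreeding
coefficient F = 1 - h_obs / (2 p (1 - p)) >= 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .synth.genotypes import MISSING


@dataclass
class SnpFilterConfig:
    min_mac: int = 40
    min_call_rate: float = 0.60
    max_het: float = 0.10
    min_inbreeding: float = 0.8

    def __post_init__(self):
        if self.min_mac < 0:
            raise ValueError("min_mac must be >= 0")
        if not 0 <= self.min_call_rate <= 1 or not 0 <= self.max_het <= 1:
            raise ValueError("rates must be in [0, 1]")


def _to_float_missing_nan(dosages) -> np.ndarray:
    d = np.asarray(dosages, dtype=float)
    d[np.asarray(dosages) == MISSING] = np.nan
    return d


def snp_stats(dosages) -> pd.DataFrame:
    """Per-SNP call rate, MAF, MAC, heterozygosity and inbreeding F.

    Allele counts use two alleles per non-missing line; heterozygosity
    is the fraction of heterozygous calls among non-missing; F is
    1 - observed het / expected het 2p(1-p) (NaN for monomorphic SNPs).
    """
    d = _to_float_missing_nan(dosages)
    n = d.shape[0]
    n_called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
        alt = np.nansum(d, axis=0)
        mac = np.minimum(alt, 2 * n_called - alt)
        het_obs = np.nansum(d == 1, axis=0) / n_called
        exp_het = 2.0 * p * (1.0 - p)
        F = 1.0 - het_obs / exp_het
    return pd.DataFrame(
        {
            "call_rate": n_called / n,
            "maf": np.minimum(p, 1 - p),
            "mac": mac,
            "het": het_obs,
            "inbreeding_F": F,
        }
    )


def filter_snps(dosages, cfg: SnpFilterConfig = SnpFilterConfig()):
    """Apply the four QC thresholds; returns (kept index array, stats).

    The stats table gains ``keep`` and ``drop_reason`` columns
    (monomorphic SNPs have undefined F and are dropped).
    """
    st = snp_stats(dosages)
    reasons = np.array([""] * len(st), dtype=object)
    mono = st.maf.to_numpy() == 0
    reasons[mono] = "monomorphic"
    low_mac = (st.mac.to_numpy() < cfg.min_mac) & ~mono
    reasons[low_mac] = "mac"
    low_cr = (st.call_rate.to_numpy() < cfg.min_call_rate) & (reasons == "")
    reasons[low_cr] = "call_rate"
    high_het = (st.het.to_numpy() > cfg.max_het) & (reasons == "")
    reasons[high_het] = "het"
    low_f = (st.inbreeding_F.to_numpy() < cfg.min_inbreeding) & (reasons == "")
    reasons[low_f] = "inbreeding"
    st["drop_reason"] = reasons
    st["keep"] = reasons == ""
    return np.flatnonzero(st["keep"].to_numpy()), st


def mean_impute(dosages) -> np.ndarray:
    """Replace missing dosages by the SNP mean (columns all-missing -> 0)."""
    d = _to_float_missing_nan(dosages)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(d, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    return np.where(np.isnan(d), mu, d)


def ld_r2(snp_a, snp_b) -> float:
    """Squared Pearson correlation of dosages over shared non-missing lines.

    Equivalent to haplotype r^2 for fully inbred lines.  NaN when either
    SNP has zero variance or fewer than two shared calls.
    """
    a = _to_float_missing_nan(snp_a)
    b = _to_float_missing_nan(snp_b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_profile(dosages, snp_info: pd.DataFrame, top_idx: int) -> pd.DataFrame:
    """r^2 of every same-chromosome SNP against the top SNP."""
    chrom = snp_info.iloc[top_idx]["chrom"]
    idx = np.flatnonzero((snp_info["chrom"] == chrom).to_numpy())
    top = np.asarray(dosages)[:, top_idx]
    r2 = np.array([ld_r2(top, np.asarray(dosages)[:, j]) for j in idx])
    out = snp_info.iloc[idx][["snp_id", "chrom", "pos"]].copy()
    out["r2"] = r2
    return out.reset_index(drop=True)


def ld_prune(
    dosages,
    snp_info: pd.DataFrame,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (PLINK-style indep-pairwise).

    Within each window of ``window`` SNPs (advanced by ``step``), while
    any retained pair has r^2 above ``r2_max`` the member of the pair
    with the smaller MAF is removed (ties: the later SNP).  SNPs must be
    position-sorted within chromosomes.  Returns retained indices.
    """
    d = mean_impute(dosages)
    maf = snp_stats(dosages)["maf"].to_numpy()
    m = d.shape[1]
    removed = np.zeros(m, dtype=bool)
    chroms = snp_info["chrom"].to_numpy()
    pos = snp_info["pos"].to_numpy()
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError(f"SNPs on chromosome {c} are not position-sorted")
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            active = win[~removed[win]]
            if len(active) > 1:
                sub = d[:, active]
                with np.errstate(invalid="ignore"):
                    cc = np.corrcoef(sub.T) ** 2
                np.fill_diagonal(cc, 0.0)
                cc = np.nan_to_num(cc)
                while True:
                    i, j = np.unravel_index(np.argmax(cc), cc.shape)
                    if cc[i, j] <= r2_max:
                        break
                    drop_local = i if (maf[active[i]], -active[i]) < (maf[active[j]], -active[j]) else j
                    removed[active[drop_local]] = True
                    cc[drop_local, :] = 0.0
                    cc[:, drop_local] = 0.0
            if start + window >= len(idx):
                break
            start += step
    return np.flatnonzero(~removed)


def kinship_vanraden(dosages) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    K = W W' / (2 * sum_j p_j (1 - p_j)) with W the dosage matrix
    centered at 2 p_j (missing mean-imputed).  Monomorphic SNPs
    contribute nothing; all-monomorphic input raises.
    """
    d = mean_impute(dosages)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1 - p)))
    if denom == 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    W = d - 2.0 * p
    return (W @ W.T) / denom


def genotype_pcs(dosages, n_pcs: int = 10) -> np.ndarray:
    """Leading principal components of the centered (mean-imputed) dosages."""
    d = mean_impute(dosages)
    W = d - d.mean(axis=0)
    U, S, _ = np.linalg.svd(W, full_matrices=False)
    return U[:, :n_pcs] * S[:n_pcs]


# -- spectral (EMMA-style) machinery ---------------------------------------

def _spectral(K: np.ndarray):
    S, U = np.linalg.eigh((K + K.T) / 2.0)
    if S.min() < -1e-8:
        warnings.warn(
            f"kinship not PSD (min eigenvalue {S.min():.2e}); clamping to zero"
        )
    S = np.clip(S, 0.0, None)
    return S, U


def _null_reml(y, X, S, U, reml: bool = True):
    """Profile (RE)ML over the ratio lambda = s2_g / s2_e on rotated data.

    Returns (s2_g, s2_e, loglik).  ``reml=False`` gives full ML (used
    for BIC covariate comparison, where fixed effects differ).
    """
    n, p = X.shape
    yr = U.T @ y
    Xr = U.T @ X

    def neg_ll(log_lam):
        lam = np.exp(log_lam)
        w = lam * S + 1.0  # V = s2_e * diag(w)
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        r = yr - Xr @ beta
        rss = float(r @ (r / w))
        if reml:
            dof = n - p
            s2e = rss / dof
            ll = -0.5 * (
                dof * np.log(2 * np.pi * s2e) + np.sum(np.log(w))
                + np.linalg.slogdet(XtWX)[1] + dof
            )
        else:
            s2e = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * s2e) + np.sum(np.log(w)) + n)
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # also consider the boundary lambda -> 0 (no genetic variance)
    if neg_ll(-12.0) < res.fun:
        lam = np.exp(-12.0)
    w = lam * S + 1.0
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    s2e = rss / (n - p if reml else n)
    ll = -neg_ll(np.log(lam))
    return lam * s2e, s2e, float(ll)


def select_covariates(
    trait: np.ndarray,
    flowering_time: np.ndarray | None,
    pcs: np.ndarray,
    K: np.ndarray,
    max_pcs: int = 10,
) -> tuple[dict, pd.DataFrame]:
    """BIC selection over {flowering time in/out} x {0..max_pcs leading PCs}.

    Each candidate set is scored with the full-ML log-likelihood of the
    null mixed model (no SNP) under the kinship K; BIC = -2 ll +
    n_param log n.  Returns (chosen, table): ``chosen`` has keys
    ``flowering_time`` (bool) and ``n_pcs``.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    S, U = _spectral(K)
    max_pcs = min(max_pcs, pcs.shape[1] if pcs is not None else 0)
    rows = []
    for use_ft in ([False, True] if flowering_time is not None else [False]):
        for k in range(max_pcs + 1):
            cols = [np.ones(n)]
            if use_ft:
                cols.append(np.asarray(flowering_time, dtype=float))
            if k:
                cols.append(pcs[:, :k])
            X = np.column_stack(cols)
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                warnings.warn("collinear covariates dropped from BIC search")
                continue
            _, _, ll = _null_reml(y, X, S, U, reml=False)
            n_param = X.shape[1] + 2  # betas + two variance components
            bic = -2.0 * ll + n_param * np.log(n)
            rows.append({"flowering_time": use_ft, "n_pcs": k, "loglik": ll, "bic": bic})
    table = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    best = table.iloc[0]
    chosen = {"flowering_time": bool(best.flowering_time), "n_pcs": int(best.n_pcs)}
    return chosen, table


def gwas_p3d(
    trait: np.ndarray,
    dosages,
    snp_info: pd.DataFrame,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """P3D univariate mixed-model scan.

    Variance components are REML-estimated once under the null model
    and fixed; every (mean-imputed) SNP is then tested with a GLS Wald
    t-test after whitening by the null covariance.  Returns a table
    with effect, SE, p, BH q and a ``significant`` flag at ``fdr``.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    d = mean_impute(dosages)
    if d.shape[0] != n or K.shape != (n, n):
        raise ValueError("lines misaligned across trait, genotypes and kinship")
    cols = [np.ones(n)]
    if covariates is not None and np.size(covariates):
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols.append(covariates)
    X = np.column_stack(cols)

    S, U = _spectral(K)
    s2g, s2e, _ = _null_reml(y, X, S, U, reml=True)
    w = s2g * S + s2e  # diagonal covariance after rotation
    sw = np.sqrt(w)
    yt = (U.T @ y) / sw
    Xt = (U.T @ X) / sw[:, None]
    Dt = (U.T @ d) / sw[:, None]

    p_fix = X.shape[1]
    dof = n - p_fix - 1
    # residualize the SNP and the trait against the fixed covariates (FWL)
    Q, _ = np.linalg.qr(Xt)
    y_res = yt - Q @ (Q.T @ yt)
    D_res = Dt - Q @ (Q.T @ Dt)
    ss = np.einsum("ij,ij->j", D_res, D_res)
    const = ss <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (D_res.T @ y_res) / ss
        rss = float(y_res @ y_res) - beta**2 * ss
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / ss)
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[const] = se[const] = tstat[const] = np.nan
    pvals[const] = np.nan

    out = snp_info[["snp_id", "chrom", "pos"]].copy().reset_index(drop=True)
    out["effect"] = beta
    out["se"] = se
    out["p"] = pvals
    out["q"] = np.nan
    tested = ~np.isnan(pvals)
    out.loc[tested, "q"] = bh_fdr(pvals[tested])
    out["significant"] = out["q"] <= fdr
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
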