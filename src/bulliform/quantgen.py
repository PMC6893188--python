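"""REML mixed models for the augmented incomplete-block trial.

The plot-level model has grand mean and check status as fixed effects
and (up to) environment, genotype, genotype-by-environment, incomplete
block within environment, and column within environment as independent
random effects:

    y = X beta + sum_i Z_i u_i + e,   u_i ~ N(0, s2_i I),  e ~ N(0, s2_e I)

Variance components are estimated by REML with average-information
updates and EM fallback steps (EM is monotone in the REML
log-likelihood, so every accepted iteration increases it);
non-negativity is enforced by projection to the boundary.  The
asymptotic covariance of the estimates is the inverse average
information, which feeds delta-method standard errors for
heritability.

Model reduction follows backward elimination: each removable random
term is tested with a likelihood-ratio test against the boundary-
corrected null (an equal mixture of chi-square 0 and 1), and the least
significant term above alpha is dropped until all remaining terms are
significant.  Genotype is never removed.

Heritability (Holland-style):

    plot basis (single environment):  h2 = s2_G / (s2_G + s2_e)
    line-mean basis (across):         h2 = s2_G / (s2_G + s2_GE/nE + s2_e/(nE*nr))

with harmonic-mean numbers of environments (nE) and replicates per
line and environment (nr) computed from the realized data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

RANDOM_TERMS = ("env", "genotype", "gxe", "block", "col")
REML_TOL = 1e-6
MAX_ITER = 500


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the mixed model and on which data scope."""

    random_terms: tuple[str, ...] = RANDOM_TERMS
    scope: str = "both"  # "both" or one environment label
    trait: str = "trait"

    def __post_init__(self):
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if self.scope != "both" and "gxe" in self.random_terms:
            raise ValueError("G x E term requires scope='both'")
        if self.scope != "both" and "env" in self.random_terms:
            raise ValueError("environment term requires scope='both'")

    def drop(self, term: str) -> "ModelSpec":
        return replace(self, random_terms=tuple(t for t in self.random_terms if t != term))


def single_env_spec(env: str, trait: str = "trait") -> ModelSpec:
    return ModelSpec(random_terms=("genotype", "block", "col"), scope=env, trait=trait)


def _indicator(labels: pd.Series, mask=None) -> tuple[np.ndarray, list]:
    """Indicator matrix over the sorted level set; rows where ``mask`` is
    False (check plots, for genotype-type terms) are all-zero."""
    labels = labels.astype(str)
    if mask is None:
        mask = np.ones(len(labels), dtype=bool)
    levels = sorted(labels[mask].unique())
    lut = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, (lab, ok) in enumerate(zip(labels, mask)):
        if ok:
            Z[i, lut[lab]] = 1.0
    return Z, levels


def build_design(pheno: pd.DataFrame, spec: ModelSpec):
    """Response y, fixed design X (mean + check dummies), and the random
    design matrices for each term in the spec."""
    df = pheno if spec.scope == "both" else pheno[pheno["env"] == spec.scope]
    if len(df) == 0:
        raise ValueError(f"no plots in scope {spec.scope!r}")
    df = df.reset_index(drop=True)
    y = df[spec.trait].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    df, y = df[keep].reset_index(drop=True), y[keep]

    checks = sorted(df.loc[df.is_check, "entry"].unique())
    X_cols = [np.ones(len(df))]
    names = ["mean"]
    for c in checks:
        X_cols.append((df.entry == c).to_numpy(dtype=float))
        names.append(f"check:{c}")
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = names[int(np.linalg.matrix_rank(X))]
        raise ValueError(f"singular fixed design; aliased term near {aliased!r}")

    exp_mask = (~df.is_check).to_numpy()
    Z, levels = {}, {}
    for term in spec.random_terms:
        if term == "env":
            Z[term], levels[term] = _indicator(df.env)
        elif term == "genotype":
            Z[term], levels[term] = _indicator(df.entry, mask=exp_mask)
        elif term == "gxe":
            Z[term], levels[term] = _indicator(df.entry + ":" + df.env, mask=exp_mask)
        elif term == "block":
            Z[term], levels[term] = _indicator(df.env + ":" + df.block)
        elif term == "col":
            Z[term], levels[term] = _indicator(df.env + ":" + df.col)
    for term in spec.random_terms:
        if Z[term].shape[1] < 2:
            raise ValueError(f"random term {term!r} has fewer than 2 levels")
    return df, y, X, names, Z, levels


@dataclass
class MixedModelFit:
    spec: ModelSpec
    varcomp: dict[str, float]  # per random term + "residual"
    varcomp_cov: np.ndarray  # inverse average information, term order + residual
    loglik: float
    beta: np.ndarray
    beta_names: list
    blups: dict[str, pd.Series]  # per random term
    data: pd.DataFrame = field(repr=False)
    n_obs: int = 0
    converged: bool = True
    ll_path: list = field(default_factory=list, repr=False)

    @property
    def varcomp_order(self) -> list:
        return list(self.spec.random_terms) + ["residual"]

    def line_blups(self) -> pd.Series:
        """BLUPs of experimental lines (genetic values as deviations)."""
        return self.blups["genotype"]


class ConvergenceError(RuntimeError):
    pass


def _reml_quantities(y, X, M_list, theta):
    """Log-likelihood, P y, traces and solves for one theta."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, M in zip(theta[:-1], M_list):
        V += t * M
    c, low = cho_factor(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(n))
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cx = cho_factor(XtViX)
    logdet_X = np.linalg.slogdet(XtViX)[1]
    Viy = Vinv @ y
    XtViy = X.T @ Viy
    beta = cho_solve(cx, XtViy)
    Py = Viy - ViX @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_V + logdet_X + yPy + (n - p) * np.log(2 * np.pi))

    def apply_P(v):
        Viv = Vinv @ v
        return Viv - ViX @ cho_solve(cx, X.T @ Viv)

    # tr(P M_i): via tr(Vinv M) - tr((X'VinvX)^-1 X'Vinv M Vinv X)
    traces = []
    for M in M_list + [None]:
        if M is None:
            tr_VinvM = float(np.trace(Vinv))
            ViMViX = Vinv @ ViX
        else:
            tr_VinvM = float(np.sum(Vinv * M))  # M symmetric
            ViMViX = Vinv @ (M @ ViX)
        corr = float(np.trace(cho_solve(cx, X.T @ ViMViX)))
        traces.append(tr_VinvM - corr)
    return {
        "ll": ll, "Py": Py, "traces": np.array(traces), "apply_P": apply_P,
        "beta": beta, "XtViX_chol": cx, "Vinv": Vinv,
    }


def _score_ai(y, M_list, q, theta):
    """REML score vector and average-information matrix at theta."""
    Py = q["Py"]
    w = [M @ Py for M in M_list] + [Py]
    yPMPy = np.array([float(Py @ wi) for wi in w])
    score = -0.5 * (q["traces"] - yPMPy)
    Pw = [q["apply_P"](wi) for wi in w]
    k = len(w)
    AI = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(w[i] @ Pw[j])
    return score, AI


def fit_reml(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    tol: float = REML_TOL,
    max_iter: int = MAX_ITER,
) -> MixedModelFit:
    """REML fit of the specified mixed model.

    Average-information steps with step-halving; whenever an AI step
    fails to increase the restricted log-likelihood an EM step (which is
    guaranteed monotone) is taken instead.  Components are kept
    non-negative by projection; convergence is a log-likelihood change
    below ``tol``.
    """
    df, y, X, names, Z, levels = build_design(pheno, spec)
    n = len(y)
    terms = list(spec.random_terms)
    M_list = [Z[t] @ Z[t].T for t in terms]
    q_sizes = np.array([Z[t].shape[1] for t in terms] + [n], dtype=float)

    var_y = float(np.var(y)) or 1.0
    floor = 1e-10 * var_y
    k = len(terms) + 1
    theta = np.full(k, var_y / k)

    q = _reml_quantities(y, X, M_list, theta)
    ll_path = [q["ll"]]
    converged = False
    for _ in range(max_iter):
        score, AI = _score_ai(y, M_list, q, theta)
        # EM step (always available, monotone)
        Py = q["Py"]
        yPMPy = np.array(
            [float(Py @ (M @ Py)) for M in M_list] + [float(Py @ Py)]
        )
        em_theta = theta + (theta**2 / q_sizes) * (yPMPy - q["traces"])
        em_theta = np.maximum(em_theta, floor)

        accepted = False
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(8):
                cand = np.maximum(theta + step * delta, floor)
                try:
                    q_new = _reml_quantities(y, X, M_list, cand)
                except np.linalg.LinAlgError:
                    step /= 2
                    continue
                if q_new["ll"] >= ll_path[-1] - 1e-12:
                    theta, q = cand, q_new
                    accepted = True
                    break
                step /= 2
        if not accepted:
            try:
                q_new = _reml_quantities(y, X, M_list, em_theta)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError(f"variance matrix singular: {exc}") from exc
            if q_new["ll"] < ll_path[-1] - 1e-8:
                # EM should be monotone; tiny decreases can occur at the
                # floor boundary — stop there.
                ll_path.append(q_new["ll"])
                theta, q = em_theta, q_new
                converged = True
                break
            theta, q = em_theta, q_new
        ll_path.append(q["ll"])
        if abs(ll_path[-1] - ll_path[-2]) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations "
            f"(last log-likelihood change {ll_path[-1] - ll_path[-2]:.2e})"
        )

    _, AI = _score_ai(y, M_list, q, theta)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)

    theta = np.where(theta <= 2 * floor, 0.0, theta)
    varcomp = {t: float(v) for t, v in zip(terms + ["residual"], theta)}
    blups = {}
    for t, Zt in ((t, Z[t]) for t in terms):
        u = varcomp[t] * (Zt.T @ q["Py"])
        blups[t] = pd.Series(u, index=levels[t], name=t)
    return MixedModelFit(
        spec=spec, varcomp=varcomp, varcomp_cov=cov, loglik=float(q["ll"]),
        beta=q["beta"], beta_names=names, blups=blups, data=df, n_obs=n,
        converged=True, ll_path=ll_path,
    )


def lrt_boundary_pvalue(ll_full: float, ll_reduced: float) -> float:
    """One-component LRT p-value with the 1/2 chi2_0 + 1/2 chi2_1 mixture."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    if stat == 0.0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(stat, df=1))


def reduce_model(
    pheno: pd.DataFrame,
    full_spec: ModelSpec,
    alpha: float = 0.05,
    protected: tuple[str, ...] = ("genotype",),
) -> tuple[MixedModelFit, list]:
    """Backward elimination of non-significant random terms.

    Returns (final fit, history of (term, p-value, removed?)).
    """
    spec = full_spec
    fit = fit_reml(pheno, spec)
    history = []
    while True:
        candidates = [t for t in spec.random_terms if t not in protected]
        if not candidates:
            break
        pvals = {}
        for t in candidates:
            reduced = fit_reml(pheno, spec.drop(t))
            pvals[t] = lrt_boundary_pvalue(fit.loglik, reduced.loglik)
        worst = max(pvals, key=lambda t: (pvals[t], t))
        if pvals[worst] <= alpha:
            for t, p in pvals.items():
                history.append((t, p, False))
            break
        history.append((worst, pvals[worst], True))
        spec = spec.drop(worst)
        fit = fit_reml(pheno, spec)
    return fit, history


def screen_outliers(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove observations with significant Studentized deleted residuals.

    The mixed model is fitted by REML, the data are whitened with the
    Cholesky factor of the fitted marginal covariance (making the
    transformed errors i.i.d.), and standard deleted residuals of the
    whitened fixed-effects regression are compared with the two-sided t
    critical value at ``alpha`` with n - p - 1 degrees of freedom
    (single pass).  Returns (cleaned table in the model scope, flags).
    """
    if alpha < 0 or alpha >= 1:
        raise ValueError("alpha must be in [0, 1)")
    df, y, X, _, Z, _ = build_design(pheno, spec)
    fit = fit_reml(pheno, spec)
    n, p = X.shape
    V = fit.varcomp["residual"] * np.eye(n)
    for t in spec.random_terms:
        V += fit.varcomp[t] * (Z[t] @ Z[t].T)
    L = np.linalg.cholesky(V)
    y_w = np.linalg.solve(L, y)
    X_w = np.linalg.solve(L, X)

    Q, _ = np.linalg.qr(X_w)
    h = np.sum(Q * Q, axis=1)
    beta, *_ = np.linalg.lstsq(X_w, y_w, rcond=None)
    e = y_w - X_w @ beta
    dof = n - p - 1
    sse = float(e @ e)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_del = e * np.sqrt(dof / np.maximum(sse * (1 - h) - e**2, 1e-300))
    a = alpha / n if bonferroni else alpha
    crit = np.inf if a == 0 else stats.t.ppf(1 - a / 2, dof)
    flagged = np.abs(t_del) > crit

    flags = df.assign(studentized_deleted=t_del, outlier=flagged)
    cleaned = df[~flagged].reset_index(drop=True)
    lost = set(df.loc[~df.is_check, "entry"]) - set(cleaned.loc[~cleaned.is_check, "entry"])
    if lost:
        warnings.warn(f"outlier removal emptied line(s) {sorted(lost)}; dropped downstream")
    return cleaned, flags


@dataclass
class HeritabilityEstimate:
    basis: str  # "plot" or "line-mean"
    estimate: float
    se: float
    detail: dict = field(default_factory=dict)


def _delta_se(grad: dict, cov: np.ndarray, order: list) -> float:
    g = np.array([grad.get(t, 0.0) for t in order])
    return float(np.sqrt(max(0.0, g @ cov @ g)))


def heritability(fit: MixedModelFit, basis: str) -> HeritabilityEstimate:
    """Heritability with a first-order delta-method standard error."""
    vc = fit.varcomp
    order = fit.varcomp_order
    if "genotype" not in vc:
        raise ValueError("fit has no genotype component")
    s2g = vc["genotype"]
    s2e = vc["residual"]
    if basis == "plot":
        denom = s2g + s2e
        if denom == 0:
            raise ValueError("all components zero: heritability undefined")
        h2 = s2g / denom
        grad = {"genotype": s2e / denom**2, "residual": -s2g / denom**2}
        se = _delta_se(grad, fit.varcomp_cov, order)
        return HeritabilityEstimate("plot", h2, se, {"n_E": 1, "n_r": 1})
    if basis != "line-mean":
        raise ValueError(f"unknown basis {basis!r}")
    if fit.spec.scope != "both":
        raise ValueError("line-mean heritability needs the across-environment fit")

    exp = fit.data[~fit.data.is_check]
    per_line_envs = exp.groupby("entry")["env"].nunique()
    n_e = stats.hmean(per_line_envs)
    reps = exp.groupby(["entry", "env"]).size()
    n_r = stats.hmean(reps)

    s2ge = vc.get("gxe", 0.0)
    denom = s2g + s2ge / n_e + s2e / (n_e * n_r)
    if denom == 0:
        raise ValueError("all components zero: heritability undefined")
    h2 = s2g / denom
    grad = {
        "genotype": (denom - s2g) / denom**2,
        "gxe": -s2g / (n_e * denom**2),
        "residual": -s2g / (n_e * n_r * denom**2),
    }
    se = _delta_se(grad, fit.varcomp_cov, order)
    return HeritabilityEstimate("line-mean", h2, se, {"n_E": float(n_e), "n_r": float(n_r)})
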