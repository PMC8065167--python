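"""Cohort statistics: myopia grouping, random-intercept mixed models with
Satterthwaite degrees of freedom, pairwise group contrasts, Edwards
semi-partial R², Pearson correlation and patient-level ANOVA/chi-squared.

The eye-level models are linear mixed models with a single patient-level
random intercept, estimated by REML. Degrees of freedom for t- and F-tests
use Satterthwaite's approximation: the variance of each estimated contrast
variance is propagated through its gradient with respect to the two
variance components, whose asymptotic covariance comes from the inverse
expected REML information. Multi-df F-tests combine per-eigenvector
Satterthwaite dfs in the usual way (sum of ν/(ν−2) terms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "MYOPIA_GROUPS",
    "assign_myopia_group",
    "LMMResult",
    "fit_lmm",
    "semi_partial_r2",
    "GroupComparison",
    "group_comparison",
    "patient_level_anova",
    "patient_level_chi2",
    "pearson_corr",
]

MYOPIA_GROUPS = ("no", "mild", "high")

_VAR_FLOOR = 1e-10


class SingularDesignError(ValueError):
    """Fixed-effects design is rank deficient."""


def assign_myopia_group(al_mm: float) -> str | None:
    """Axial-myopia group from axial length (mm).

    ``no`` if AL ≤ 24.0, ``mild`` if 24.0 < AL ≤ 26.0, ``high`` if
    AL > 26.0. Non-finite AL returns None (missing-data flag).
    """
    if al_mm is None or not np.isfinite(al_mm):
        return None
    if al_mm <= 0:
        raise ValueError(f"axial length must be positive, got {al_mm}")
    if al_mm <= 24.0:
        return "no"
    if al_mm <= 26.0:
        return "mild"
    return "high"


# ---------------------------------------------------------------------------
# design construction

def _build_design(
    table: pd.DataFrame, fixed: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand covariates into a design matrix with an intercept.

    Non-numeric columns become treatment-coded dummies (reference = first
    level; for ``myopia_group`` the reference is always ``no``). Returns
    the design and a term → column-names map for F-tests.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    terms: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    for name in fixed:
        col = table[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
            terms[name] = [name]
        else:
            levels = list(pd.unique(col.astype(str)))
            if name == "myopia_group":
                levels = [g for g in MYOPIA_GROUPS if g in levels]
            term_cols = []
            for lev in levels[1:]:
                cname = f"{name}[{lev}]"
                cols[cname] = (col.astype(str) == lev).to_numpy(dtype=float)
                term_cols.append(cname)
            terms[name] = term_cols
    X = pd.DataFrame(cols, index=table.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # identify aliased columns by QR pivoting on correlations
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise SingularDesignError(f"singular fixed-effects design; aliased columns: {aliased}")
    return X, terms


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


# ---------------------------------------------------------------------------
# Satterthwaite machinery (single random intercept)

@dataclass
class _GLSMachinery:
    X: np.ndarray
    beta: np.ndarray
    C: np.ndarray  # (X' V^-1 X)^-1
    Vinv: np.ndarray
    group_idx: list[np.ndarray]
    varcomp_cov: np.ndarray  # asymptotic cov of (tau2, sigma2) (2x2 or 1x1)
    boundary: bool  # patient variance at zero: treated as pure OLS variance
    tau2: float
    sigma2: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _machinery(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, tau2: float, sigma2: float
) -> _GLSMachinery:
    n, p = X.shape
    uniq, inv = np.unique(groups, return_inverse=True)
    Z = np.zeros((n, uniq.size))
    Z[np.arange(n), inv] = 1.0
    G = Z @ Z.T
    sigma2 = max(float(sigma2), _VAR_FLOOR)
    tau2 = max(float(tau2), 0.0)
    boundary = tau2 <= 1e-8 * (tau2 + sigma2) or uniq.size == n
    V = sigma2 * np.eye(n) + tau2 * G
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    C = np.linalg.inv(XtVX)
    beta = C @ X.T @ Vinv @ y
    P = Vinv - Vinv @ X @ C @ X.T @ Vinv
    if boundary:
        i22 = 0.5 * np.sum(P * P)
        cov = np.array([[1.0 / i22]])
    else:
        PZ = P @ Z
        ZtPZ = Z.T @ PZ
        i11 = 0.5 * np.sum(ZtPZ * ZtPZ)
        i12 = 0.5 * np.sum(PZ * PZ)
        i22 = 0.5 * np.sum(P * P)
        info = np.array([[i11, i12], [i12, i22]])
        cov = np.linalg.inv(info)
    group_idx = [np.where(inv == k)[0] for k in range(uniq.size)]
    return _GLSMachinery(
        X=X, beta=beta, C=C, Vinv=Vinv, group_idx=group_idx,
        varcomp_cov=cov, boundary=boundary, tau2=tau2, sigma2=sigma2,
    )


def _contrast_var_df(m: _GLSMachinery, c: np.ndarray) -> tuple[float, float]:
    """Variance of c'β̂ and its Satterthwaite df."""
    g = float(c @ m.C @ c)
    w = m.Vinv @ (m.X @ (m.C @ c))
    grad_sigma = float(w @ w)
    if m.boundary:
        grad = np.array([grad_sigma])
    else:
        grad_tau = float(sum(np.sum(w[idx]) ** 2 for idx in m.group_idx))
        grad = np.array([grad_tau, grad_sigma])
    var_g = float(grad @ m.varcomp_cov @ grad)
    if var_g <= 0 or g <= 0:
        return g, float(m.n - m.p)
    return g, 2.0 * g * g / var_g


def _f_test(m: _GLSMachinery, L: np.ndarray) -> tuple[float, int, float]:
    """F statistic and Satterthwaite denominator df for H0: Lβ = 0."""
    q = L.shape[0]
    M = L @ m.C @ L.T
    Lb = L @ m.beta
    F = float(Lb @ np.linalg.solve(M, Lb)) / q
    evals, evecs = np.linalg.eigh(M)
    nus = []
    for i in range(q):
        ci = evecs[:, i] @ L
        _, nu = _contrast_var_df(m, ci)
        nus.append(nu)
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if E > q:
        df2 = 2.0 * E / (E - q)
    else:
        df2 = float(m.n - m.p)
    return F, q, df2


# ---------------------------------------------------------------------------
# model fitting

@dataclass
class LMMResult:
    """Inference from a random-intercept linear mixed model.

    ``params``/``se``/``df``/``pvalues``/``conf_int`` are per-coefficient
    (Satterthwaite t-inference); ``ftests`` has one row per model term with
    the marginal F, its dfs, the p-value and the Edwards semi-partial R²
    computed from that F.
    """

    outcome: str
    params: pd.Series
    se: pd.Series
    df: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    ftests: pd.DataFrame  # index: term; columns: F, df1, df2, pvalue, r2
    tau2: float  # patient random-intercept variance
    sigma2: float  # residual variance
    n_patients: int
    n_eyes: int
    n_dropped: int
    boundary: bool
    terms: dict[str, list[str]] = field(default_factory=dict)


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    fixed: list[str] | None = None,
    grouping: str = "patient_id",
    alpha: float = 0.05,
) -> LMMResult:
    """Fit an eye-level linear mixed model with a patient random intercept.

    REML estimation (via statsmodels ``MixedLM``), Satterthwaite degrees of
    freedom for every t- and F-test, and 95% CIs from the t quantile at the
    contrast's df. Rows with missing outcome/covariates are dropped
    listwise and counted in ``n_dropped``. When every patient contributes a
    single eye the model collapses exactly to OLS (the intercept variance
    is not identifiable and is pinned at zero, giving the OLS residual df).
    """
    fixed = list(fixed or [])
    used_cols = [outcome, grouping] + fixed
    data = table[used_cols].dropna()
    n_dropped = len(table) - len(data)
    if data[grouping].nunique() < 2:
        raise ValueError("need at least 2 patients to fit a mixed model")
    X, terms = _build_design(data, fixed)
    y = data[outcome].to_numpy(dtype=float)
    groups = data[grouping].to_numpy()
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    n, p = Xa.shape

    singleton = data.groupby(grouping).size().max() == 1
    y_var = float(np.var(y))
    if singleton or y_var <= _VAR_FLOOR:
        ols = sm.OLS(y, Xa).fit()
        tau2, sigma2 = 0.0, float(ols.scale)
    else:
        model = sm.MixedLM(y, Xa, groups=groups)
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "cg"):
                try:
                    fit = model.fit(reml=True, method=method, maxiter=500)
                except Exception:
                    continue
                if fit.converged:
                    break
        if fit is None:
            raise RuntimeError("mixed model estimation failed to converge")
        tau2 = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
        sigma2 = float(fit.scale)

    m = _machinery(Xa, y, groups, tau2, sigma2)
    est, ses, dfs, ts, ps, lo, hi = [], [], [], [], [], [], []
    for j in range(p):
        c = np.zeros(p)
        c[j] = 1.0
        g, nu = _contrast_var_df(m, c)
        se_j = float(np.sqrt(g))
        t_j = float(m.beta[j] / se_j) if se_j > 0 else np.nan
        est.append(float(m.beta[j]))
        ses.append(se_j)
        dfs.append(nu)
        ts.append(t_j)
        ps.append(float(2 * sps.t.sf(abs(t_j), nu)) if np.isfinite(t_j) else np.nan)
        q = sps.t.ppf(1 - alpha / 2, nu)
        lo.append(float(m.beta[j] - q * se_j))
        hi.append(float(m.beta[j] + q * se_j))

    frows = {}
    for term, tcols in terms.items():
        if term == "Intercept" or not tcols:
            continue
        L = np.zeros((len(tcols), p))
        for i, cn in enumerate(tcols):
            L[i, names.index(cn)] = 1.0
        F, df1, df2 = _f_test(m, L)
        if y_var <= _VAR_FLOOR:
            pval = np.nan
        else:
            pval = float(sps.f.sf(F, df1, df2))
        frows[term] = {
            "F": F,
            "df1": df1,
            "df2": df2,
            "pvalue": pval,
            "r2": _edwards_r2(F, df1, df2),
        }
    ftests = pd.DataFrame.from_dict(frows, orient="index")

    idx = pd.Index(names)
    return LMMResult(
        outcome=outcome,
        params=pd.Series(est, index=idx),
        se=pd.Series(ses, index=idx),
        df=pd.Series(dfs, index=idx),
        tvalues=pd.Series(ts, index=idx),
        pvalues=pd.Series(ps, index=idx),
        conf_int=pd.DataFrame({"lower": lo, "upper": hi}, index=idx),
        ftests=ftests,
        tau2=m.tau2 if not m.boundary else 0.0,
        sigma2=m.sigma2,
        n_patients=int(data[grouping].nunique()),
        n_eyes=int(len(data)),
        n_dropped=n_dropped,
        boundary=m.boundary,
        terms=terms,
    )


def _edwards_r2(F: float, df1: float, df2: float) -> float:
    """Edwards semi-partial R² from a marginal F statistic:
    R² = (ν₁/ν₂·F) / (1 + ν₁/ν₂·F)."""
    if not np.isfinite(F) or F < 0 or df2 <= 0:
        return np.nan
    x = df1 / df2 * F
    return float(x / (1.0 + x))


def semi_partial_r2(res: LMMResult, effect: str) -> float:
    """Edwards semi-partial R² of a fitted effect, in [0, 1]."""
    if effect not in res.ftests.index:
        raise KeyError(
            f"effect {effect!r} not in fitted model terms {list(res.ftests.index)}"
        )
    return float(res.ftests.loc[effect, "r2"])


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class GroupComparison:
    """Three-group myopia comparison of one eye-level outcome."""

    outcome: str
    overall_F: float
    overall_df: tuple[float, float]
    overall_p: float
    group_means: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_estimates: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    model: LMMResult


def group_comparison(
    table: pd.DataFrame,
    outcome: str,
    adjust: list[str] | None = None,
    grouping: str = "patient_id",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare an eye-level outcome across the three myopia groups.

    Fits the random-intercept mixed model with myopia group as a 3-level
    fixed factor (plus any adjustment covariates), reports the overall
    Satterthwaite F-test and the three pairwise t-tests of regression
    parameters. No multiplicity adjustment is applied; significance markers
    use p < ``alpha``.
    """
    adjust = list(adjust or [])
    present = [g for g in MYOPIA_GROUPS if g in set(table["myopia_group"].dropna())]
    if len(present) < 2:
        raise ValueError("group comparison requires at least 2 myopia groups")
    res = fit_lmm(table, outcome, ["myopia_group"] + adjust, grouping=grouping)
    names = list(res.params.index)
    p = len(names)
    # contrast vectors for pairwise differences under treatment coding
    def col(level: str) -> np.ndarray:
        c = np.zeros(p)
        cname = f"myopia_group[{level}]"
        if cname in names:
            c[names.index(cname)] = 1.0
        return c

    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1 :]]
    # rebuild machinery for arbitrary contrasts
    data = table[[outcome, grouping, "myopia_group"] + adjust].dropna()
    X, _ = _build_design(data, ["myopia_group"] + adjust)
    m = _machinery(
        X.to_numpy(dtype=float),
        data[outcome].to_numpy(dtype=float),
        data[grouping].to_numpy(),
        res.tau2,
        res.sigma2,
    )
    y_var = float(np.var(data[outcome].to_numpy(dtype=float)))
    pairwise_p, pairwise_est, signif = {}, {}, {}
    for a, b in pairs:
        c = col(b) - col(a)
        g, nu = _contrast_var_df(m, c)
        estimate = float(c @ m.beta)
        if y_var <= _VAR_FLOOR or g <= 0:
            pv = np.nan
        else:
            tstat = estimate / np.sqrt(g)
            pv = float(2 * sps.t.sf(abs(tstat), nu))
        pairwise_p[(a, b)] = pv
        pairwise_est[(a, b)] = estimate
        signif[(a, b)] = bool(pv < alpha) if np.isfinite(pv) else False

    frow = res.ftests.loc["myopia_group"]
    means = {
        g: float(data.loc[data["myopia_group"] == g, outcome].mean()) for g in present
    }
    return GroupComparison(
        outcome=outcome,
        overall_F=float(frow["F"]),
        overall_df=(float(frow["df1"]), float(frow["df2"])),
        overall_p=float(frow["pvalue"]) if np.isfinite(frow["pvalue"]) else np.nan,
        group_means=means,
        pairwise_p=pairwise_p,
        pairwise_estimates=pairwise_est,
        significant=signif,
        model=res,
    )


def patient_level_anova(
    table: pd.DataFrame, column: str, grouping: str = "patient_id"
) -> tuple[float, float]:
    """One-way ANOVA of a patient-level variable across myopia groups.

    Uses one row per patient (the first-listed eye's record). Returns
    (F, p)."""
    per_patient = table.dropna(subset=[column]).groupby(grouping).first()
    samples = [
        per_patient.loc[per_patient["myopia_group"] == g, column].to_numpy(dtype=float)
        for g in MYOPIA_GROUPS
        if (per_patient["myopia_group"] == g).any()
    ]
    if len(samples) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    F, p = sps.f_oneway(*samples)
    return float(F), float(p)


def patient_level_chi2(
    table: pd.DataFrame, column: str, grouping: str = "patient_id"
) -> tuple[float, float]:
    """Chi-squared test of a categorical patient-level variable vs group."""
    per_patient = table.dropna(subset=[column]).groupby(grouping).first()
    ct = pd.crosstab(per_patient[column], per_patient["myopia_group"])
    chi2, p, _, _ = sps.chi2_contingency(ct)
    return float(chi2), float(p)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if xa.size < 3:
        raise ValueError("correlation requires at least 3 observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("inputs must be finite")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)
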