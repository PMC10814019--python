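"""Group-comparison statistics for microvessel biomarker cohorts.

Implements the study's machinery: two-sided Wilcoxon rank-sum tests,
Mann-Whitney AUC with a stratified percentile-bootstrap confidence
interval, Firth (Jeffreys-penalized) logistic regression with a
structural-missingness linear predictor b0 + b1*X1 + b2*X1*X2 tested by a
2-df likelihood-ratio test, pairwise-complete Pearson correlations, and a
thickness-restricted sensitivity analysis. All p-values are reported
unadjusted for multiple testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth.cohort import BIOMARKER_COLUMNS, BRANCHING_BIOMARKERS

__all__ = [
    "wilcoxon_rank_sum",
    "auc_mw",
    "auc_ci_bootstrap",
    "FirthFit",
    "firth_logistic",
    "missingness_lrt",
    "pearson_pairwise",
    "run_group_analysis",
    "GroupAnalysis",
]

ALWAYS_MEASURABLE = [c for c in BIOMARKER_COLUMNS if c not in BRANCHING_BIOMARKERS]


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode='exact'`` enumerates the permutation null (valid for small,
    tie-free samples); ``'asymptotic'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact when
    n_x + n_y <= 20 and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # identical constants: no evidence of any difference
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if method == "exact" and has_ties:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def auc_mw(x, y) -> float:
    """Mann-Whitney AUC: P(x > y) + 0.5 P(x = y), x the positive class."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def _auc_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise AUC for resample matrices xs (B, n1) and ys (B, n2)."""
    gt = (xs[:, :, None] > ys[:, None, :]).sum(axis=(1, 2))
    eq = (xs[:, :, None] == ys[:, None, :]).sum(axis=(1, 2))
    return (gt + 0.5 * eq) / (xs.shape[1] * ys.shape[1])


def auc_ci_bootstrap(x, y, B: int = 2000, seed: int = 0, level: float = 0.95):
    """Stratified nonparametric bootstrap percentile CI for the AUC."""
    if B < 200:
        raise ValueError("B must be >= 200")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    chunk = max(1, int(5e6 // max(1, x.size * y.size)))
    for b0 in range(0, B, chunk):
        nb = min(chunk, B - b0)
        xs = x[rng.integers(0, x.size, size=(nb, x.size))]
        ys = y[rng.integers(0, y.size, size=(nb, y.size))]
        aucs[b0 : b0 + nb] = _auc_rows(xs, ys)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass
class FirthFit:
    """Result of a Jeffreys-penalized logistic fit (optionally with an LRT)."""

    coef: np.ndarray
    penalized_loglik: float
    converged: bool
    n_iter: int
    lrt_stat: float = float("nan")
    lrt_df: int = 0
    lrt_p: float = float("nan")
    columns: list = field(default_factory=list)


def _penalized_loglik(y, X, beta) -> float:
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(y @ np.log(p + eps) + (1 - y) @ np.log(1 - p + eps))
    w = p * (1 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    y, X, max_iter: int = 50, tol: float = 1e-6, free: np.ndarray | None = None
) -> FirthFit:
    """Firth-penalized logistic regression by Newton iteration.

    Maximizes l(b) + 0.5 log det I(b); the penalized score is
    U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij with h the hat values of
    the weighted design. Coefficients stay finite under complete separation.

    ``free`` marks the coefficients to estimate; the others are held at 0
    while the Jeffreys penalty keeps using the full design's information —
    the constrained fit that makes penalized likelihood-ratio tests between
    nested models comparable.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("design matrix rows must match y")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("y must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    n, k = X.shape
    free = np.ones(k, dtype=bool) if free is None else np.asarray(free, dtype=bool)
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat values of W^(1/2) X (X' W X)^(-1) X' W^(1/2), full design
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score[free])) < tol:
            converged = True
            break
        step = np.zeros(k)
        step[free] = np.linalg.solve(info[np.ix_(free, free)], score[free])
        # step-halving on the penalized likelihood
        ll0 = _penalized_loglik(y, X, beta)
        lam = 1.0
        for _ in range(12):
            if _penalized_loglik(y, X, beta + lam * step) >= ll0 - 1e-10:
                break
            lam /= 2.0
        beta = beta + lam * step

    if not converged:
        warnings.warn("Firth logistic regression did not converge; returning last iterate")
    return FirthFit(
        coef=beta,
        penalized_loglik=_penalized_loglik(y, X, beta),
        converged=converged,
        n_iter=it,
    )


def missingness_lrt(y, value, observed) -> FirthFit:
    """Joint 2-df Firth LRT for a biomarker with structural missingness.

    Full model columns {1, X1, X1*X2}: X1 the measurability indicator and X2
    the (z-scored) biomarker value, filled with 0 where unobserved — the
    fill is irrelevant because X2 enters only through X1*X2. The null is the
    intercept-only constrained fit on the same design (the Jeffreys penalty
    keeps the full information determinant), so the penalized likelihoods
    are directly comparable and the LRT is chi^2-calibrated. Redundant
    columns (e.g. X1 identically 1) are dropped with the df adjusted.
    """
    y = np.asarray(y, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if not np.isin(observed, [0.0, 1.0]).all():
        raise ValueError("observed must be a 0/1 indicator")
    value = np.asarray(value, dtype=float).ravel()
    if np.isnan(value[observed == 1]).any():
        raise ValueError("value must be present wherever observed == 1")

    x2 = np.zeros_like(value)
    obs = observed == 1
    if obs.any():
        v = value[obs]
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        x2[obs] = (v - v.mean()) / sd if sd > 0 else 0.0
    n = y.size
    cols = [np.ones(n), observed, observed * x2]
    names = ["intercept", "X1", "X1*X2"]

    keep_cols, keep_names = [np.ones(n)], ["intercept"]
    for c, nm in zip(cols[1:], names[1:]):
        cand = np.column_stack(keep_cols + [c])
        if np.linalg.matrix_rank(cand) > len(keep_cols):
            keep_cols.append(c)
            keep_names.append(nm)
        else:
            warnings.warn(f"column {nm} is redundant in the missingness design; dropped")
    X_full = np.column_stack(keep_cols)
    df = X_full.shape[1] - 1
    full = firth_logistic(y, X_full)
    free0 = np.zeros(X_full.shape[1], dtype=bool)
    free0[0] = True
    null = firth_logistic(y, X_full, free=free0)
    lrt = max(0.0, 2.0 * (full.penalized_loglik - null.penalized_loglik))
    p = float(sps.chi2.sf(lrt, df)) if df > 0 else float("nan")
    full.lrt_stat = lrt
    full.lrt_df = df
    full.lrt_p = p
    full.columns = keep_names
    return full


def pearson_pairwise(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Entries based on fewer than ``min_pairs`` complete pairs, or on a
    constant column, are NaN; the diagonal is 1 wherever the column has any
    data.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ValueError("need at least 2 rows")
    corr = num.corr(method="pearson", min_periods=min_pairs)
    for c in num.columns:
        if num[c].notna().any():
            corr.loc[c, c] = 1.0
    return corr


@dataclass
class GroupAnalysis:
    """Tables mirroring the study layout: full-cohort comparisons, branching
    LRTs, the thickness-restricted subset, and the correlation matrix."""

    comparison: pd.DataFrame          # 8 always-measurable biomarkers
    branching: pd.DataFrame           # 4 structurally-missing biomarkers
    subset_comparison: pd.DataFrame | None
    correlations: pd.DataFrame
    thickness_cutoff_mm: float
    seed: int
    bootstrap_B: int


def _comparison_table(df: pd.DataFrame, seed: int, B: int, with_auc: bool = True) -> pd.DataFrame:
    mal = df[df["label"] == "malignant"]
    ben = df[df["label"] == "benign"]
    rows = []
    for i, bm in enumerate(ALWAYS_MEASURABLE):
        x = mal[bm].to_numpy(dtype=float)
        y = ben[bm].to_numpy(dtype=float)
        row = {
            "biomarker": bm,
            "n_malignant": x.size,
            "n_benign": y.size,
            "malignant_mean": x.mean(),
            "malignant_sd": x.std(ddof=1),
            "benign_mean": y.mean(),
            "benign_sd": y.std(ddof=1),
            "p_value": wilcoxon_rank_sum(x, y),
        }
        if with_auc:
            row["auc"] = auc_mw(x, y)
            lo, hi = auc_ci_bootstrap(x, y, B=B, seed=seed + i)
            row["auc_ci_low"], row["auc_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def run_group_analysis(
    cohort: pd.DataFrame,
    thickness_cutoff_mm: float = 2.5,
    seed: int = 0,
    bootstrap_B: int = 2000,
) -> GroupAnalysis:
    """Run the full statistical analysis on a labeled cohort table."""
    labels = set(cohort["label"].unique())
    if not {"malignant", "benign"} <= labels:
        raise ValueError("cohort must contain both malignant and benign rows")

    comparison = _comparison_table(cohort, seed=seed, B=bootstrap_B)

    y = (cohort["label"] == "malignant").to_numpy(dtype=float)
    obs = cohort["measurable_MD_BA"].to_numpy(dtype=float)
    branch_rows = []
    for bm in BRANCHING_BIOMARKERS:
        val = cohort[bm].to_numpy(dtype=float)
        fit = missingness_lrt(y, val, obs)
        mal = cohort[(cohort["label"] == "malignant") & (cohort["measurable_MD_BA"] == 1)][bm]
        ben = cohort[(cohort["label"] == "benign") & (cohort["measurable_MD_BA"] == 1)][bm]
        branch_rows.append(
            {
                "biomarker": bm,
                "n_measurable_malignant": int(mal.size),
                "n_measurable_benign": int(ben.size),
                "malignant_mean": mal.mean(),
                "malignant_sd": mal.std(ddof=1),
                "benign_mean": ben.mean(),
                "benign_sd": ben.std(ddof=1),
                "lrt_stat": fit.lrt_stat,
                "lrt_df": fit.lrt_df,
                "p_value": fit.lrt_p,
            }
        )
    branching = pd.DataFrame(branch_rows)

    sub = cohort[cohort["thickness_mm"] <= thickness_cutoff_mm]
    if (sub["label"] == "malignant").any() and (sub["label"] == "benign").any():
        subset = _comparison_table(sub, seed=seed + 1000, B=bootstrap_B, with_auc=False)
    else:
        warnings.warn("thickness cutoff empties one group; subset analysis skipped")
        subset = None

    corr = pearson_pairwise(cohort[BIOMARKER_COLUMNS])

    return GroupAnalysis(
        comparison=comparison,
        branching=branching,
        subset_comparison=subset,
        correlations=corr,
        thickness_cutoff_mm=thickness_cutoff_mm,
        seed=seed,
        bootstrap_B=bootstrap_B,
    )
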