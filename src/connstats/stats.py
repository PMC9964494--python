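"""Group inference: covariate residualization, label-permutation t-tests,
Benjamini–Hochberg FDR, demographic tests and clinical correlations.

The group comparison of every network metric follows the same recipe: the
metric is residualized on age and gender by pooled-sample OLS, a
pooled-variance two-sample t statistic is computed on the residuals, and its
significance comes from permuting the group labels (default 10,000 draws).
The two-sided permutation p uses add-one smoothing, p = (1 + #{|t*| ≥
|t_obs|}) / (1 + n_perm), so sampled permutations never report p = 0.  Global
metrics are FDR-corrected as a family of 4 (S_p, E_glob, C_p, sigma) and each
nodal metric as a family of 116 nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "adjust_covariates",
    "permutation_ttest",
    "fdr_bh",
    "compare_groups",
    "chi_square_2x2",
    "two_sample_t",
    "mann_whitney",
    "pearson_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    """One metric's group comparison: observed pooled t on residuals, sampled
    permutation p, BH-adjusted p, and raw-scale group summaries."""

    metric_name: str
    observed_t: float
    p_perm: float
    p_fdr: float
    n_perm: int
    mean_pd: float
    sd_pd: float
    mean_hc: float
    sd_hc: float


def adjust_covariates(
    values: np.ndarray, age: np.ndarray, gender: np.ndarray
) -> np.ndarray:
    """Residuals of *values* after pooled-sample OLS on intercept + age + gender.

    A degenerate covariate column (constant across subjects) is dropped with a
    warning rather than failing; residuals always sum to zero.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender, dtype=float)
    if not (len(values) == len(age) == len(gender)):
        raise ValueError("values, age and gender must have equal length")
    if len(values) < 4:
        raise ValueError("need at least 4 subjects for covariate adjustment")
    cols = [np.ones_like(values)]
    for name, col in (("age", age), ("gender", gender)):
        if np.ptp(col) == 0:
            logger.warning("covariate %s is constant; dropped from the design", name)
        else:
            cols.append(col)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx_, ny = len(x), len(y)
    sp2 = ((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx_ + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx_ + 1 / ny)))


def permutation_ttest(
    residuals: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided label-permutation test of a pooled-variance t statistic.

    Group labels are randomly reassigned *n_perm* times (uniform relabelings,
    independent across draws); p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm).
    Returns ``(observed_t, p_perm)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    mask1 = groups == names[0]
    n1 = int(mask1.sum())
    n = len(residuals)
    if n1 < 2 or n - n1 < 2:
        raise ValueError("each group needs at least 2 subjects")
    t_obs = _pooled_t(residuals[mask1], residuals[~mask1])

    rng = np.random.default_rng(seed)
    # vectorized permutation t: group-1 membership as a boolean matrix
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_mask = order < n1  # each row: a uniformly random size-n1 subset
    s = residuals.sum()
    ss = (residuals**2).sum()
    s1 = perm_mask @ residuals
    ss1 = perm_mask @ residuals**2
    n2 = n - n1
    m1, m2 = s1 / n1, (s - s1) / n2
    var1 = (ss1 - n1 * m1**2) / (n1 - 1)
    var2 = ((ss - ss1) - n2 * m2**2) / (n2 - 1)
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = (1 + int(np.sum(np.abs(t_perm) >= abs(t_obs)))) / (1 + n_perm)
    return t_obs, float(p)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def compare_groups(
    metrics_table: pd.DataFrame,
    metric_columns: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Permutation group comparison of each metric column, FDR over the family.

    *metrics_table* needs columns ``group`` ("PD"/"HC"), ``age``,
    ``gender_code`` and the listed metric columns; the listed columns form one
    FDR family (pass the 4 global metrics together, or one nodal metric's 116
    node columns together).  Group means/SDs are reported on the raw scale.
    """
    required = {"group", "age", "gender_code"}
    if not required <= set(metrics_table.columns):
        raise ValueError(f"metrics table must contain columns {sorted(required)}")
    groups = metrics_table["group"].to_numpy()
    age = metrics_table["age"].to_numpy(dtype=float)
    gender = metrics_table["gender_code"].to_numpy(dtype=float)
    pd_mask = groups == "PD"
    results = []
    rng = np.random.default_rng(seed)
    for name in metric_columns:
        vals = metrics_table[name].to_numpy(dtype=float)
        resid = adjust_covariates(vals, age, gender)
        t_obs, p = permutation_ttest(
            resid, groups, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        # groups sorts as HC < PD; flip so the sign convention is PD - HC
        t_obs = -t_obs
        results.append(
            PermutationResult(
                metric_name=name,
                observed_t=t_obs,
                p_perm=p,
                p_fdr=np.nan,
                n_perm=n_perm,
                mean_pd=float(vals[pd_mask].mean()),
                sd_pd=float(vals[pd_mask].std(ddof=1)),
                mean_hc=float(vals[~pd_mask].mean()),
                sd_hc=float(vals[~pd_mask].std(ddof=1)),
            )
        )
    adj = fdr_bh([r.p_perm for r in results])
    return [
        PermutationResult(
            metric_name=r.metric_name,
            observed_t=r.observed_t,
            p_perm=r.p_perm,
            p_fdr=float(q),
            n_perm=r.n_perm,
            mean_pd=r.mean_pd,
            sd_pd=r.sd_pd,
            mean_hc=r.mean_hc,
            sd_hc=r.sd_hc,
        )
        for r, q in zip(results, adj)
    ]


def chi_square_2x2(table, yates: bool = False) -> float:
    """Pearson χ² on a 2×2 count table, optionally with Yates continuity
    correction (|O−E| reduced by 0.5, floored at 0)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    return float(np.sum(dev**2 / expected))


def two_sample_t(x, y, pooled: bool = True) -> float:
    """Two-sample t statistic, Student (pooled) or Welch; sign is x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if pooled:
        return _pooled_t(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t statistic undefined")
    return float(sps.ttest_ind(x, y, equal_var=False).statistic)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann–Whitney U for *x* (midrank ties) and the tie-corrected normal z.

    When every value is tied the variance is zero and z is returned as NaN
    (flagged degenerate case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least 1 observation")
    U = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return U, float("nan")
    z = (U - n1 * n2 / 2.0) / np.sqrt(var)
    return U, float(z)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
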