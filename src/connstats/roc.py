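"""Logistic classification of group from global network metrics and
permutation-validated ROC analysis.

For each global metric a logistic model ``group ~ metric + age + gender`` is
fit by maximum likelihood (IRLS), the ROC curve of the in-sample fitted
probabilities is built, and the AUROC's significance is assessed by permuting
the group labels across the whole sample (default 1000 times) and refitting
the full model each time.  Following the original counting rule, the
permutation p is the plain fraction of permutations with AUROC strictly
greater than the observed one — no smoothing, so p = 0 is possible.

The "optimal" operating point maximizes Youden's J = sensitivity +
specificity − 1, ties broken toward higher sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogisticFit",
    "RocResult",
    "fit_logistic",
    "roc_auc",
    "optimal_threshold",
    "permutation_auroc_p",
    "roc_analysis",
]

logger = logging.getLogger(__name__)

_COEF_CAP = 30.0  # cap on standardized coefficients under separation


@dataclass(frozen=True)
class LogisticFit:
    """ML logistic fit: coefficients on the original predictor scale
    (intercept first) and in-sample fitted probabilities."""

    coef: np.ndarray
    fitted: np.ndarray
    converged: bool
    separated: bool
    n_iter: int


@dataclass(frozen=True)
class RocResult:
    metric_name: str
    auroc: float
    curve: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)
    threshold: float
    sensitivity: float
    specificity: float
    p_perm: float | None
    n_perm: int
    degenerate: bool = False


def fit_logistic(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression of binary *y* on *X*.

    *X* is the design without intercept (one is added).  Predictors are
    standardized internally for numerical stability; coefficients are
    reported on the original scale.  Fitting is iteratively reweighted least
    squares, stopping when the largest coefficient change is below 1e-8 or
    after 100 iterations.  Perfect separation is flagged and the standardized
    coefficients capped at ±30 rather than diverging.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("y and X have incompatible shapes")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    if np.any(sd_x == 0):
        raise ValueError("constant predictor column in the design")
    Z = np.column_stack([np.ones(len(y)), (X - mu_x) / sd_x])

    beta = np.zeros(Z.shape[1])
    converged = separated = False
    it = 0
    for it in range(1, 101):
        eta = np.clip(Z @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        if np.all(w < 1e-12):
            separated = True
            break
        # IRLS step: solve Z' W Z delta = Z'(y - p)
        WZ = Z * w[:, None]
        try:
            delta = np.linalg.solve(Z.T @ WZ + 1e-12 * np.eye(Z.shape[1]), Z.T @ (y - p))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta_new = beta + delta
        if np.abs(beta_new).max() > _COEF_CAP:
            separated = True
            beta = np.clip(beta_new, -_COEF_CAP, _COEF_CAP)
            break
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        if step < 1e-8:
            converged = True
            break
    if separated:
        logger.warning("perfect or quasi-separation: coefficients capped")
    eta = np.clip(Z @ beta, -35, 35)
    fitted = 1.0 / (1.0 + np.exp(-eta))
    # map standardized coefficients back to the original predictor scale
    slopes = beta[1:] / sd_x
    intercept = beta[0] - np.sum(slopes * mu_x)
    return LogisticFit(
        coef=np.concatenate([[intercept], slopes]),
        fitted=fitted,
        converged=converged,
        separated=separated,
        n_iter=it,
    )


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve and AUROC of *scores* for binary labels *y* (1 = case).

    The AUROC equals the Mann–Whitney probability (#{case > control} + half
    the ties) / (n_case · n_control); the curve sweeps all distinct score
    thresholds, returning (1 − specificity, sensitivity) points from (0, 0)
    to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    cases = scores[y == 1]
    controls = scores[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    wins = np.sum(cases[:, None] > controls[None, :])
    ties = np.sum(cases[:, None] == controls[None, :])
    auroc = (wins + 0.5 * ties) / (len(cases) * len(controls))

    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        sens = np.mean(cases >= t)
        spec = np.mean(controls < t)
        pts.append((1 - spec, sens))
    pts.append((1.0, 1.0))
    curve = np.unique(np.array(pts), axis=0)
    order = np.lexsort((curve[:, 1], curve[:, 0]))
    return curve[order], float(auroc)


def optimal_threshold(
    scores: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, bool]:
    """Score threshold maximizing Youden's J; ties go to higher sensitivity.

    Returns ``(threshold, sensitivity, specificity, degenerate)``; degenerate
    is True when no threshold beats J = 0 (e.g. all scores identical).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    cases = scores[y == 1]
    controls = scores[y == 0]
    best = (-np.inf, -np.inf, np.nan, np.nan, np.nan)  # (J, sens, thr, sens, spec)
    for t in np.unique(scores):
        sens = float(np.mean(cases >= t))
        spec = float(np.mean(controls < t))
        j = sens + spec - 1
        if (j, sens) > best[:2]:
            best = (j, sens, float(t), sens, spec)
    degenerate = best[0] <= 0
    return best[2], best[3], best[4], degenerate


def permutation_auroc_p(
    y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for the AUROC of the logistic model of *y* on *X*.

    Only the label vector is shuffled — each subject's covariates stay
    attached to their metric — and the full model is refit per permutation.
    p = #{AUROC_perm > AUROC_obs} / n_perm (strict inequality, unsmoothed).
    Errors out if more than 10% of permutation fits fail outright.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    fit = fit_logistic(y, X)
    _, auc_obs = roc_auc(fit.fitted, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    failures = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            fit_p = fit_logistic(y_perm, X)
            _, auc_p = roc_auc(fit_p.fitted, y_perm)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        if auc_p > auc_obs:
            exceed += 1
    if failures > 0.1 * n_perm:
        raise RuntimeError(
            f"{failures}/{n_perm} permutation fits failed: degenerate design"
        )
    return exceed / n_perm


def roc_analysis(
    metric_name: str,
    metric: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> RocResult:
    """Full ROC pipeline for one metric: logistic fit with age and gender as
    covariates, curve/AUROC, Youden threshold, and permutation p."""
    X = np.column_stack([metric, age, gender])
    fit = fit_logistic(y, X)
    curve, auroc = roc_auc(fit.fitted, y)
    thr, sens, spec, degenerate = optimal_threshold(fit.fitted, y)
    p = permutation_auroc_p(y, X, n_perm=n_perm, seed=seed) if n_perm else None
    return RocResult(
        metric_name=metric_name,
        auroc=auroc,
        curve=curve,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        p_perm=p,
        n_perm=n_perm,
        degenerate=degenerate,
    )
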