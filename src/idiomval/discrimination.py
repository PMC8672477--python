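"""Discrimination: ROC curve, C-statistic with CI, and the Gmean operating point.

The C-statistic (equivalently the area under the ROC curve) is the
probability that a randomly chosen case receives a higher predicted risk
than a randomly chosen non-case, with ties counted half.  Confidence
intervals use the DeLong asymptotic variance by default; a seeded
percentile bootstrap is available for small samples.  The Gmean operating
point maximises sqrt(sensitivity x specificity) over the distinct-risk
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["DiscriminationResult", "roc_points", "auc_with_ci", "best_gmean"]


@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)
    gmean_best: float
    gmean_threshold: float
    ci_method: str = "delong"


def _split(risks, outcomes):
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    if risks.shape != outcomes.shape:
        raise ValueError("risks and outcomes must have equal length")
    cases = risks[outcomes == 1]
    controls = risks[outcomes == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one event and one non-event")
    return cases, controls


def roc_points(risks, outcomes) -> np.ndarray:
    """ROC curve over distinct thresholds, as (1 - specificity, sensitivity).

    Points run from (0, 0) (threshold above the maximum risk) to (1, 1)
    (everyone predicted positive), both coordinates non-decreasing.  No
    interpolated operating points are added.
    """
    cases, controls = _split(risks, outcomes)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        # strict classification: positive iff risk > t, plus the all-positive
        # end point reached when t falls below the minimum risk
        fpr.append(np.mean(controls >= t))
        tpr.append(np.mean(cases >= t))
    pts = np.column_stack([fpr, tpr])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    """P(case risk > control risk) + 0.5 P(tie), via midranks."""
    m, n = cases.size, controls.size
    ranks = rankdata(np.concatenate([cases, controls]))
    return (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    m, n = cases.size, controls.size
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v01 = (all_ranks[:m] - case_ranks) / n  # per-case placement values
    v10 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per-control
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return s01 / m + s10 / n


def auc_with_ci(
    risks,
    outcomes,
    alpha: float = 0.05,
    *,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> DiscriminationResult:
    """C-statistic with a two-sided (1 - alpha) confidence interval.

    ``ci_method`` is ``"delong"`` (asymptotic, default) or ``"bootstrap"``
    (percentile over patient resamples; requires ``seed``).  The interval is
    clipped to [0, 1].
    """
    cases, controls = _split(risks, outcomes)
    auc = _auc_mann_whitney(cases, controls)
    if ci_method == "delong":
        se = float(np.sqrt(_delong_variance(cases, controls)))
        z = norm.ppf(1 - alpha / 2)
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        risks = np.asarray(risks, dtype=float)
        outcomes = np.asarray(outcomes)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, risks.size, risks.size)
            y = outcomes[idx]
            if y.min() == y.max():
                continue  # single-class resample carries no AUC
            stats.append(_auc_mann_whitney(risks[idx][y == 1], risks[idx][y == 0]))
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    threshold, gmean = best_gmean(risks, outcomes)
    return DiscriminationResult(
        auc=float(auc),
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        roc_points=roc_points(risks, outcomes),
        gmean_best=gmean,
        gmean_threshold=threshold,
        ci_method=ci_method,
    )


def best_gmean(risks, outcomes) -> tuple[float, float]:
    """Threshold maximising sqrt(sensitivity x specificity), and its value.

    Every distinct predicted risk is evaluated as a strict threshold
    (positive iff risk > t).  Ties are broken toward the lower threshold,
    i.e. toward higher sensitivity.
    """
    cases, controls = _split(risks, outcomes)
    thresholds = np.unique(np.concatenate([cases, controls]))
    sens = np.array([np.mean(cases > t) for t in thresholds])
    spec = np.array([np.mean(controls <= t) for t in thresholds])
    gmean = np.sqrt(sens * spec)
    best = int(np.argmax(gmean))  # argmax returns the first, hence lowest, threshold
    return float(thresholds[best]), float(gmean[best])
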