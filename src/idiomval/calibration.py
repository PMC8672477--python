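"""The calibration hierarchy for an externally validated risk model.

Four levels, increasingly demanding:

* **Mean calibration** (calibration-in-the-large): observed event rate
  versus mean predicted risk, as an observed/expected ratio and a signed
  relative difference.
* **Weak calibration**: the calibration intercept (an intercept-only
  logistic fit of the outcome with the model's linear predictor as a fixed
  offset; target 0) and the calibration slope (a logistic fit of the
  outcome on the linear predictor with free intercept; target 1), each with
  a Wald confidence interval.
* **Moderate calibration**: a flexible curve — locally weighted linear
  regression (loess, tricube weights) of the binary outcome on predicted
  risk, evaluated on a 100-point grid over the observed risk range.
* **Risk-group calibration**: mean predicted risk versus observed event
  fraction within each group of a risk-group scheme.

The logistic fits are performed by an in-module iteratively reweighted
least squares (IRLS) routine so that the calibration engine has no model
dependencies and its convergence and error behaviour are fully specified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .model import RiskGroupScheme, assign_risk_group

__all__ = [
    "MeanCalibrationResult",
    "WeakCalibrationResult",
    "FlexibleCurve",
    "LogisticFit",
    "mean_calibration",
    "fit_logistic",
    "weak_calibration",
    "flexible_curve",
    "group_calibration",
]


@dataclass(frozen=True)
class MeanCalibrationResult:
    """Observed event rate versus mean predicted risk.

    ``oe_ratio`` is observed/expected; ``relative_diff_pct`` is the signed
    percent by which the mean prediction exceeds the observed rate
    (positive = overestimation).  The two are algebraically linked:
    oe_ratio = 1 / (1 + relative_diff_pct/100).
    """

    observed_prevalence: float
    mean_predicted: float
    oe_ratio: float
    relative_diff_pct: float


def mean_calibration(risks, outcomes) -> MeanCalibrationResult:
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if risks.size == 0:
        raise ValueError("empty cohort")
    observed = float(outcomes.mean())
    predicted = float(risks.mean())
    return MeanCalibrationResult(
        observed_prevalence=observed,
        mean_predicted=predicted,
        oe_ratio=observed / predicted,
        relative_diff_pct=100.0 * (predicted - observed) / observed,
    )


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic coefficients with standard errors."""

    coef: np.ndarray
    se: np.ndarray
    n_iter: int
    converged: bool


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect or quasi-perfect separation)."""


def fit_logistic(
    responses,
    covariate=None,
    offset=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic regression by IRLS (Newton-Raphson on the log-likelihood).

    The design always contains an intercept; ``covariate`` adds one slope
    column; ``offset`` enters the linear predictor with coefficient fixed at
    one.  Convergence requires the maximum absolute score below ``tol``
    within ``max_iter`` iterations.  Standard errors come from the inverse
    observed information.

    Raises ``ValueError`` for degenerate responses, ``SeparationError`` when
    the estimates diverge, ``RuntimeError`` on non-convergence.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("responses must be a non-empty 1-d array")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("responses must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("responses are all identical; intercept is infinite")
    cols = [np.ones_like(y)]
    if covariate is not None:
        x = np.asarray(covariate, dtype=float)
        if x.shape != y.shape or not np.all(np.isfinite(x)):
            raise ValueError("covariate must be finite and match responses in length")
        cols.append(x)
    X = np.column_stack(cols)
    off = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if off.shape != y.shape:
        raise ValueError("offset must match responses in length")

    beta = np.zeros(X.shape[1])
    info = None
    for it in range(1, max_iter + 1):
        eta = X @ beta + off
        p = expit(eta)
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        if np.max(np.abs(score)) < tol:
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            # the score also vanishes when fitted probabilities saturate at
            # 0/1 along a separating direction; the exploding curvature
            # betrays that the MLE is actually infinite
            if np.max(np.abs(beta)) > 30.0 or np.max(se) > 100.0:
                raise SeparationError(
                    "quasi-separation: estimates unbounded, standard errors diverge"
                )
            return LogisticFit(coef=beta, se=se, n_iter=it, converged=True)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix: separation or a degenerate covariate"
            )
        beta = beta + step
        if np.max(np.abs(beta)) > 50.0:
            raise SeparationError(
                "coefficients diverged (|beta| > 50): data are separated"
            )
    raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")


@dataclass(frozen=True)
class WeakCalibrationResult:
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]


def weak_calibration(lp, outcomes, alpha: float = 0.05) -> WeakCalibrationResult:
    """Calibration intercept and slope of a model's linear predictor.

    Intercept: logistic fit of the outcome with ``lp`` as fixed offset
    (target 0 — no systematic over/underestimation; negative means the model
    overestimates).  Slope: coefficient of ``lp`` in a free-intercept fit
    (target 1; below 1 means risk estimates are too extreme).  Wald
    two-sided (1 - alpha) intervals.
    """
    lp = np.asarray(lp, dtype=float)
    z = norm.ppf(1 - alpha / 2)
    fit_a = fit_logistic(outcomes, offset=lp)
    a, se_a = fit_a.coef[0], fit_a.se[0]
    fit_b = fit_logistic(outcomes, covariate=lp)
    b, se_b = fit_b.coef[1], fit_b.se[1]
    return WeakCalibrationResult(
        intercept=float(a),
        intercept_ci=(float(a - z * se_a), float(a + z * se_a)),
        slope=float(b),
        slope_ci=(float(b - z * se_b), float(b + z * se_b)),
    )


@dataclass(frozen=True)
class FlexibleCurve:
    """Loess-smoothed observed event probability over the predicted-risk range."""

    grid: np.ndarray
    smoothed_observed: np.ndarray
    span: float


def flexible_curve(risks, outcomes, span: float = 0.75, n_grid: int = 100) -> FlexibleCurve:
    """Flexible calibration curve: loess of the binary outcome on predicted risk.

    Degree-1 locally weighted regression with tricube weights over the
    nearest ``ceil(span * n)`` points, no robustness iterations, evaluated on
    ``n_grid`` equally spaced points spanning the observed risk range.  The
    smoothed values are clipped to [0, 1].  Requires n >= 50 and
    span in (0, 1].
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    x = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.size < 50:
        raise ValueError(f"flexible calibration needs n >= 50, got {x.size}")
    grid = np.linspace(x.min(), x.max(), n_grid)
    k = max(2, int(np.ceil(span * x.size)))
    fitted = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        # bandwidth = distance to the k-th nearest point
        h = np.partition(d, k - 1)[k - 1]
        if h == 0.0:
            # mass of ties at x0 (e.g. constant risks): local mean
            fitted[i] = y[d == 0.0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0.0:
            fitted[i] = ym
        else:
            slope = (w * (x - xm) * (y - ym)).sum() / sxx
            fitted[i] = ym + slope * (x0 - xm)
    return FlexibleCurve(
        grid=grid, smoothed_observed=np.clip(fitted, 0.0, 1.0), span=span
    )


def group_calibration(risks, outcomes, scheme: RiskGroupScheme) -> "pandas.DataFrame":  # noqa: F821
    """Observed versus predicted risk within each group of ``scheme``.

    Returns one row per group label (in scheme order) with the group size,
    mean predicted risk, observed event fraction and a ``zero_events`` flag.
    Empty groups keep n = 0 with NaN rates — the very-low group of a scheme
    derived on the same data is expected to be event-free, not an error.
    """
    import pandas as pd

    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    groups = assign_risk_group(risks, scheme)
    rows = []
    for label in scheme.labels:
        mask = groups == label
        n = int(mask.sum())
        if n == 0:
            rows.append(
                {
                    "risk_group": label,
                    "n": 0,
                    "mean_predicted": float("nan"),
                    "observed_rate": float("nan"),
                    "zero_events": True,
                }
            )
            continue
        events = outcomes[mask].sum()
        rows.append(
            {
                "risk_group": label,
                "n": n,
                "mean_predicted": float(risks[mask].mean()),
                "observed_rate": float(events / n),
                "zero_events": bool(events == 0),
            }
        )
    return pd.DataFrame(rows)
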