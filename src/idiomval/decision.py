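"""Decision-curve and clinical-impact analysis in avoided-investigation units.

With "investigate all" as the standard of care for IDA, the useful currency
of a risk model is the unnecessary invasive investigations it avoids.  At a
risk threshold R (the risk at which a patient is indifferent between
investigating and not, R = C/(C+B) for investigation cost C and benefit B),
the standardised net benefit of an opt-out policy is

    sNB(R) = TNR_R - (rho/(1-rho)) * ((1-R)/R) * FNR_R

where rho is the event prevalence, TNR_R the specificity and FNR_R the miss
rate when patients with predicted risk > R are investigated.  The reference
strategies are degenerate classifications: "investigate all" has
TNR = FNR = 0 (sNB identically 0) and "investigate no-one" has TNR = FNR = 1.

Clinical impact curves restate the same policy per 1000 patients: how many
would be called low risk (risk <= R) and how many of those are true
negatives, with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecisionCurve",
    "ClinicalImpactPoint",
    "standardized_net_benefit",
    "snb_none",
    "decision_curve",
    "clinical_impact",
    "cost_benefit_ratio",
]


def _check(risks, outcomes, R: float):
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    if risks.shape != outcomes.shape:
        raise ValueError("risks and outcomes must have equal length")
    if not 0.0 < R < 1.0:
        raise ValueError(f"risk threshold must lie in (0, 1), got {R}")
    events = outcomes == 1
    if not events.any() or events.all():
        raise ValueError("need at least one event and one non-event")
    return risks, events


def standardized_net_benefit(risks, outcomes, R: float) -> float:
    """sNB of "investigate iff predicted risk > R" against investigate-all."""
    risks, events = _check(risks, outcomes, R)
    rho = events.mean()
    negative = risks <= R
    tnr = np.mean(negative[~events])  # specificity at R
    fnr = np.mean(negative[events])  # miss rate at R
    return float(tnr - (rho / (1.0 - rho)) * ((1.0 - R) / R) * fnr)


def snb_none(rho: float, R: float) -> float:
    """sNB of "investigate no-one" (TNR = FNR = 1): 1 - (rho/(1-rho))((1-R)/R)."""
    return float(1.0 - (rho / (1.0 - rho)) * ((1.0 - R) / R))


@dataclass(frozen=True)
class DecisionCurve:
    """sNB of the model and both reference strategies over a threshold grid.

    ``threshold_of_superiority`` is the largest grid threshold at which the
    model's sNB is at least that of both references (NaN when the model is
    nowhere superior).
    """

    thresholds: np.ndarray
    snb_model: np.ndarray
    snb_all: np.ndarray
    snb_none: np.ndarray
    threshold_of_superiority: float

    def to_frame(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "snb_model": self.snb_model,
                "snb_all": self.snb_all,
                "snb_none": self.snb_none,
            }
        )


def default_grid(r_max: float = 0.30, step: float = 0.005) -> np.ndarray:
    """Threshold grid 0.005 .. r_max in steps of 0.005 (covers the clinically
    debated range for GI investigation in IDA)."""
    n = int(round(r_max / step))
    return np.round(np.arange(1, n + 1) * step, 10)


def decision_curve(risks, outcomes, thresholds=None) -> DecisionCurve:
    """Evaluate model/all/none standardised net benefit over a grid."""
    if thresholds is None:
        thresholds = default_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be non-empty and strictly ascending")
    if thresholds[0] <= 0.0 or thresholds[-1] >= 1.0:
        raise ValueError("thresholds must lie strictly within (0, 1)")
    risks_a, events = _check(risks, outcomes, float(thresholds[0]))
    rho = events.mean()
    model = np.array([standardized_net_benefit(risks, outcomes, R) for R in thresholds])
    none = np.array([snb_none(rho, R) for R in thresholds])
    all_ = np.zeros_like(model)
    superior = model >= np.maximum(all_, none)
    tos = float(thresholds[superior][-1]) if superior.any() else float("nan")
    return DecisionCurve(
        thresholds=thresholds,
        snb_model=model,
        snb_all=all_,
        snb_none=none,
        threshold_of_superiority=tos,
    )


@dataclass(frozen=True)
class ClinicalImpactPoint:
    """Per-1000-patient low-risk and true-negative counts at one threshold."""

    threshold: float
    low_risk_per_1000: float
    low_risk_ci: tuple[float, float]
    true_neg_per_1000: float
    true_neg_ci: tuple[float, float]


def clinical_impact(
    risks,
    outcomes,
    R: float,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ClinicalImpactPoint:
    """Patients per 1000 deemed low risk (risk <= R), and true negatives among
    them, with seeded percentile-bootstrap confidence intervals."""
    risks, events = _check(risks, outcomes, R)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if seed is None:
        raise ValueError("clinical_impact requires an explicit seed")
    low = risks <= R
    tn = low & ~events
    n = risks.size
    rng = np.random.default_rng(seed)
    boot_low = np.empty(n_boot)
    boot_tn = np.empty(n_boot)
    for b in range(n_boot):  # one resample at a time: bounded memory at large n
        idx = rng.integers(0, n, size=n)
        boot_low[b] = 1000.0 * low[idx].mean()
        boot_tn[b] = 1000.0 * tn[idx].mean()
    q = [alpha / 2, 1 - alpha / 2]
    return ClinicalImpactPoint(
        threshold=float(R),
        low_risk_per_1000=float(1000.0 * low.mean()),
        low_risk_ci=tuple(float(v) for v in np.quantile(boot_low, q)),
        true_neg_per_1000=float(1000.0 * tn.mean()),
        true_neg_ci=tuple(float(v) for v in np.quantile(boot_tn, q)),
    )


def cost_benefit_ratio(R: float) -> str:
    """Express a risk threshold as the cost:benefit ratio it implies.

    R = C/(C+B) gives C:B = R:(1-R).  When 1/R - 1 is an integer (to 1e-9)
    the ratio is reported in the reduced form "1/k" (e.g. R = 0.10 -> "1/9");
    otherwise C/B is reported as a decimal.
    """
    if not 0.0 < R < 1.0:
        raise ValueError(f"risk threshold must lie in (0, 1), got {R}")
    k = 1.0 / R - 1.0
    if abs(k - round(k)) < 1e-9:
        return f"1/{int(round(k))}"
    return f"{R / (1.0 - R):.4g}"
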