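"""Risk-group derivation from the PPV distribution, and threshold metrics.

The five IDIOM risk groups were built on the development cohort by treating
every distinct predicted risk as a classification threshold (investigate iff
risk > threshold), computing the positive predictive value (PPV) at each, and
splitting the resulting set of PPV values into quarters.  The highest
predicted risk whose PPV falls in each quarter becomes a group cut-off; the
first quarter is additionally split so that its lower half covers exactly the
thresholds with a negative predictive value (NPV) of 100% — the "very low"
group is event-free on the development data by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RISK_GROUP_LABELS, RiskGroupScheme

__all__ = [
    "ThresholdMetrics",
    "DerivedScheme",
    "confusion_at_threshold",
    "npv_floor_threshold",
    "derive_ppv_quartile_scheme",
]


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion-matrix counts and rates at one risk threshold.

    Classification is strict: a patient is predicted positive iff their
    predicted risk exceeds the threshold.  ``ppv``/``npv`` are NaN when no
    patient is predicted positive/negative.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    miss_rate: float
    ppv: float
    npv: float


def confusion_at_threshold(risks, outcomes, threshold: float) -> ThresholdMetrics:
    """Classify at ``threshold`` (positive iff risk > threshold) and tabulate.

    Requires equal-length, non-empty inputs with at least one event and one
    non-event so that sensitivity and specificity are defined.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    if risks.shape != outcomes.shape:
        raise ValueError("risks and outcomes must have equal length")
    if risks.size == 0:
        raise ValueError("empty cohort")
    events = outcomes == 1
    if not events.any() or events.all():
        raise ValueError("need at least one event and one non-event")
    positive = risks > threshold
    tp = int(np.sum(positive & events))
    fp = int(np.sum(positive & ~events))
    fn = int(np.sum(~positive & events))
    tn = int(np.sum(~positive & ~events))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return ThresholdMetrics(
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        miss_rate=1.0 - sens,
        ppv=ppv,
        npv=npv,
    )


@dataclass(frozen=True)
class DerivedScheme:
    """A risk-group scheme derived from data, with its PPV provenance.

    ``ppv_ranges`` holds the (min, max) of the PPV values observed at the
    thresholds inside each of the five groups.  ``npv_floor_threshold`` is
    the first cut-off: the highest threshold below which no development-data
    patient has the outcome (NPV = 100% by construction).
    """

    scheme: RiskGroupScheme
    ppv_ranges: tuple[tuple[float, float], ...]
    npv_floor_threshold: float


def _threshold_ppv_npv(risks: np.ndarray, outcomes: np.ndarray):
    """PPV and NPV at every distinct predicted risk used as a threshold.

    The largest risk is excluded as a threshold: nobody is predicted
    positive there and PPV is undefined.
    """
    order = np.argsort(risks, kind="mergesort")
    r = risks[order]
    y = outcomes[order].astype(float)
    distinct, last_idx = np.unique(r, return_index=True)
    # cumulative events / patients with risk <= t, for each distinct t
    cum_events = np.cumsum(y)
    cum_n = np.arange(1, r.size + 1)
    counts = np.searchsorted(r, distinct, side="right") - 1  # index of last <= t
    events_le = cum_events[counts]
    n_le = cum_n[counts]
    total_events = y.sum()
    tp = total_events - events_le  # events with risk > t
    pred_pos = r.size - n_le
    tn = n_le - events_le
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), np.nan)
        npv = np.where(n_le > 0, tn / n_le, np.nan)
    keep = pred_pos > 0
    return distinct[keep], ppv[keep], npv[keep]


def npv_floor_threshold(risks, outcomes) -> float:
    """The largest classification threshold with NPV exactly 1.

    No patient with predicted risk at or below the returned threshold has
    the outcome; below it the model's NPV is 100% by construction.  Raises
    when the lowest-risk patient is already an event.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    thresholds, _, npv = _threshold_ppv_npv(risks, outcomes.astype(int))
    event_free = npv == 1.0
    if not event_free.any():
        raise ValueError("no event-free region: the lowest predicted risk is a case")
    return float(thresholds[event_free].max())


def derive_ppv_quartile_scheme(risks, outcomes) -> DerivedScheme:
    """Derive a five-group risk scheme from the PPV-quartile procedure.

    Steps, on a development cohort of predicted risks and binary outcomes:

    1. At every distinct predicted risk ``t`` (taken as a strict threshold),
       compute the PPV among patients with risk > ``t``.
    2. Split the resulting multiset of PPV values into quarters at its
       quartiles (linear interpolation between order statistics, the default
       "type 7" convention).
    3. Map each quarter back to a threshold range through the running
       maximum of PPV over ascending thresholds.  Raw PPV is not monotone —
       above the bulk of the cohort it is estimated from a handful of
       patients and collapses towards 0 or 1 — so the monotone envelope is
       what makes "the highest predicted risk in each PPV quarter" well
       defined.  Cut-offs 2-4 are the highest thresholds whose envelope PPV
       stays within quarters 1-3 respectively.
    4. Cut-off 1 splits the first quarter at the NPV = 100% boundary: the
       highest threshold with no event at or below it
       (:func:`npv_floor_threshold`).

    Requires >= 100 records and >= 10 events; smaller cohorts produce
    degenerate PPV distributions.  Raises ``ValueError`` with a diagnostic
    when a quarter contains no threshold or the cut-offs fail to ascend
    (e.g. perfectly separated data, where the event-free region swallows the
    whole first quarter).
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    if risks.shape != outcomes.shape:
        raise ValueError("risks and outcomes must have equal length")
    if risks.size < 100:
        raise ValueError(f"need >= 100 records to derive a scheme, got {risks.size}")
    n_events = int(np.sum(outcomes == 1))
    if n_events < 10:
        raise ValueError(f"need >= 10 events to derive a scheme, got {n_events}")

    thresholds, ppv, npv = _threshold_ppv_npv(risks, outcomes.astype(int))
    q1, q2, q3 = np.quantile(ppv, [0.25, 0.5, 0.75])
    envelope = np.maximum.accumulate(ppv)  # thresholds are ascending

    def boundary(q: float, what: str) -> float:
        mask = envelope <= q
        if not mask.any():
            raise ValueError(
                f"degenerate PPV distribution: no threshold in {what} "
                f"(quartiles {q1:.4g}/{q2:.4g}/{q3:.4g})"
            )
        return float(thresholds[mask].max())

    c2 = boundary(q1, "PPV quarter 1")
    c3 = boundary(q2, "PPV quarters 1-2")
    c4 = boundary(q3, "PPV quarters 1-3")
    event_free = npv == 1.0
    if not event_free.any():
        raise ValueError("no event-free region: the lowest predicted risk is a case")
    c1 = float(thresholds[event_free].max())
    cutoffs = (c1, c2, c3, c4)
    if not (c1 < c2 < c3 < c4):
        raise ValueError(
            f"derived cut-offs are not strictly ascending: {cutoffs}; the "
            "NPV=1 region or a PPV quarter is degenerate (e.g. separated data)"
        )

    group_masks = [
        thresholds <= c1,
        (thresholds > c1) & (thresholds <= c2),
        (thresholds > c2) & (thresholds <= c3),
        (thresholds > c3) & (thresholds <= c4),
        thresholds > c4,
    ]
    ppv_ranges = tuple(
        (float(ppv[m].min()), float(ppv[m].max())) if m.any() else (float("nan"),) * 2
        for m in group_masks
    )
    scheme = RiskGroupScheme(cutoffs=cutoffs, labels=RISK_GROUP_LABELS, name="derived")
    return DerivedScheme(scheme=scheme, ppv_ranges=ppv_ranges, npv_floor_threshold=c1)


def scheme_report(derived: DerivedScheme) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate a derived scheme: group label, PPV range and risk cut-off.

    Percentages are formatted at this reporting layer only.
    """
    import pandas as pd

    cutoffs = derived.scheme.cutoffs
    upper = [f"<= {100 * c:.2f}%" for c in cutoffs] + [f"> {100 * cutoffs[-1]:.2f}%"]
    rows = []
    for label, (lo, hi), bound in zip(derived.scheme.labels, derived.ppv_ranges, upper):
        rows.append(
            {
                "risk_group": label,
                "ppv_range_pct": f"[{100 * lo:.1f}, {100 * hi:.1f}]",
                "risk_cutoff": bound,
            }
        )
    return pd.DataFrame(rows)
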