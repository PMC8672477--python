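"""The consolidated external-validation report.

``run_validation`` orchestrates the whole pipeline on one cohort table:
scoring, discrimination, the calibration hierarchy (mean, weak, flexible,
group) and decision-curve analysis, and collects the results into a single
serialisable :class:`ValidationReport`.  Percent formatting happens only
here; every module below works in probability fractions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    MeanCalibrationResult,
    WeakCalibrationResult,
    flexible_curve,
    group_calibration,
    mean_calibration,
    weak_calibration,
)
from .decision import DecisionCurve, decision_curve, default_grid
from .discrimination import DiscriminationResult, auc_with_ci
from .model import (
    DEFAULT_PRESET,
    PUBLISHED_SCHEME,
    CoefficientSet,
    RiskGroupScheme,
    get_coefficients,
    linear_predictor,
    odds_ratios,
    score_cohort,
)
from .stratification import derive_ppv_quartile_scheme

__all__ = ["ValidationReport", "run_validation", "format_percent"]


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Format a probability fraction as a percentage, rounding half-up."""
    q = Decimal(10) ** -decimals
    value = (Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value}%"


@dataclass(frozen=True)
class ValidationReport:
    """Everything the validation pipeline measured on one cohort."""

    n: int
    n_events: int
    prevalence: float
    covariate_summary: dict  # per-variable median / min / max
    coefficient_preset: str
    odds_ratios: dict
    scheme_name: str
    scheme_cutoffs: tuple
    discrimination: DiscriminationResult
    mean_calibration: MeanCalibrationResult
    weak_calibration: WeakCalibrationResult
    group_calibration: pd.DataFrame
    decision: DecisionCurve
    threshold_of_superiority: float
    flexible_curve_path: str | None
    decision_curve_path: str | None
    roc_points_path: str | None
    seed: int | None
    version: str = __version__

    def to_dict(self) -> dict:
        """Plain-types view of the report (JSON-serialisable)."""
        disc = self.discrimination
        mc = self.mean_calibration
        wc = self.weak_calibration
        return {
            "cohort": {
                "n": self.n,
                "events": self.n_events,
                "prevalence_pct": format_percent(self.prevalence),
                "covariates": self.covariate_summary,
            },
            "model": {
                "coefficient_preset": self.coefficient_preset,
                "odds_ratios": {
                    k: {kk: round(vv, 2) for kk, vv in v.items() if kk != "beta"}
                    for k, v in self.odds_ratios.items()
                },
            },
            "scheme": {
                "name": self.scheme_name,
                "cutoffs_pct": [format_percent(c) for c in self.scheme_cutoffs],
            },
            "discrimination": {
                "auc_pct": format_percent(disc.auc, 0),
                "auc": disc.auc,
                "ci": [disc.ci_low, disc.ci_high],
                "ci_method": disc.ci_method,
                "gmean_best": disc.gmean_best,
                "gmean_threshold": disc.gmean_threshold,
            },
            "calibration": {
                "mean": {
                    "observed_prevalence": mc.observed_prevalence,
                    "mean_predicted": mc.mean_predicted,
                    "oe_ratio": mc.oe_ratio,
                    "relative_diff_pct": round(mc.relative_diff_pct),
                },
                "weak": {
                    "intercept": wc.intercept,
                    "intercept_ci": list(wc.intercept_ci),
                    "slope": wc.slope,
                    "slope_ci": list(wc.slope_ci),
                },
                "groups": self.group_calibration.to_dict(orient="records"),
            },
            "decision": {
                "threshold_of_superiority": self.threshold_of_superiority,
            },
            "exports": {
                "flexible_curve": self.flexible_curve_path,
                "decision_curve": self.decision_curve_path,
                "roc_points": self.roc_points_path,
            },
            "seed": self.seed,
            "version": self.version,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _covariate_summary(cohort: pd.DataFrame) -> dict:
    out = {"male_fraction": float(np.mean(cohort["sex"]))}
    for var in ("age", "hb", "mcv"):
        x = np.asarray(cohort[var], dtype=float)
        out[var] = {
            "median": float(np.median(x)),
            "min": float(x.min()),
            "max": float(x.max()),
        }
    return out


def run_validation(
    cohort: pd.DataFrame,
    coef: CoefficientSet | str = DEFAULT_PRESET,
    scheme: RiskGroupScheme | str = "published",
    *,
    span: float = 0.75,
    grid_max: float = 0.30,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    strict_ranges: bool = False,
) -> ValidationReport:
    """Run the full external-validation pipeline on a cohort with outcomes.

    ``scheme`` is the published five-group scheme by default; pass
    ``"derive"`` to re-derive cut-offs on this cohort via the PPV-quartile
    procedure, or any :class:`RiskGroupScheme`.  When ``out_dir`` is given,
    the ROC points, flexible calibration curve and decision curve are written
    there as CSV files and their paths recorded in the report.
    """
    if isinstance(coef, str):
        coef = get_coefficients(coef)
    if "outcome" not in cohort.columns:
        raise ValueError("validation requires a cohort with outcomes")
    outcomes = np.asarray(cohort["outcome"], dtype=int)
    if outcomes.min() == outcomes.max():
        raise ValueError("validation needs at least one event and one non-event")

    scored = score_cohort(cohort, coef, PUBLISHED_SCHEME, strict=strict_ranges)
    risks = np.asarray(scored["risk"], dtype=float)
    lp = np.asarray(scored["linear_predictor"], dtype=float)

    if isinstance(scheme, str):
        if scheme == "published":
            scheme_obj = PUBLISHED_SCHEME
        elif scheme == "derive":
            scheme_obj = derive_ppv_quartile_scheme(risks, outcomes).scheme
        else:
            raise ValueError(f"unknown scheme {scheme!r} (use 'published' or 'derive')")
    else:
        scheme_obj = scheme

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"validation stage {name!r} failed: {exc}") from exc

    disc = _stage("discrimination", auc_with_ci, risks, outcomes)
    mc = _stage("mean_calibration", mean_calibration, risks, outcomes)
    wc = _stage("weak_calibration", weak_calibration, lp, outcomes)
    curve = _stage("flexible_calibration", flexible_curve, risks, outcomes, span=span)
    groups = _stage("group_calibration", group_calibration, risks, outcomes, scheme_obj)
    dca = _stage("decision_analysis", decision_curve, risks, outcomes, default_grid(grid_max))

    flex_path = dca_path = roc_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        roc_path = str(out_dir / "roc_points.csv")
        pd.DataFrame(
            disc.roc_points, columns=["one_minus_specificity", "sensitivity"]
        ).to_csv(roc_path, index=False)
        flex_path = str(out_dir / "flexible_calibration.csv")
        pd.DataFrame(
            {"predicted_risk": curve.grid, "smoothed_observed": curve.smoothed_observed}
        ).to_csv(flex_path, index=False)
        dca_path = str(out_dir / "decision_curve.csv")
        dca.to_frame().to_csv(dca_path, index=False)

    return ValidationReport(
        n=len(cohort),
        n_events=int(outcomes.sum()),
        prevalence=float(outcomes.mean()),
        covariate_summary=_covariate_summary(cohort),
        coefficient_preset=coef.label,
        odds_ratios=odds_ratios(coef),
        scheme_name=scheme_obj.name,
        scheme_cutoffs=tuple(scheme_obj.cutoffs),
        discrimination=disc,
        mean_calibration=mc,
        weak_calibration=wc,
        group_calibration=groups,
        decision=dca,
        threshold_of_superiority=dca.threshold_of_superiority,
        flexible_curve_path=flex_path,
        decision_curve_path=dca_path,
        roc_points_path=roc_path,
        seed=seed,
        version=__version__,
    )
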