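"""The IDIOM logistic risk score and its published risk-group scheme.

The IDIOM score predicts the probability of an underlying gastrointestinal
malignancy in adults with confirmed iron deficiency anaemia (IDA) from four
routinely available variables: sex, age at presentation (years), haemoglobin
concentration (Hb, g/l) and mean cell volume (MCV, fl).  The score is a
binary logistic model,

    logit P(GI malignancy) = b0 + b_sex * sex + b_age * age
                             + b_mcv * MCV + b_hb * Hb

with sex coded 1 for male, 0 for female.  Risk rises with age and male sex
and falls with higher Hb and MCV.

Three coefficient presets are bundled:

``penalised_printed``
    The Lasso-penalised equation exactly as published:
    (-1.84, 0.89, 0.05, -0.03, -0.06).
``penalised_or_consistent``  (default)
    Identical except b_hb = -0.03, the value implied by the published
    per-g/l odds ratio of 1.03 and by the reported mean predicted risks.
    The published equation's b_hb = -0.06 is inconsistent with both; the
    two variants are kept side by side rather than silently merging them.
``full_model``
    The unpenalised fit: (-1.84, 0.94, 0.06, -0.03, -0.03).

Predicted risks are carried internally as probability fractions in (0, 1);
conversion to percentages happens only in the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "CoefficientSet",
    "COEFFICIENT_PRESETS",
    "DEFAULT_PRESET",
    "get_coefficients",
    "coefficients_from_config",
    "RiskGroupScheme",
    "PUBLISHED_SCHEME",
    "RISK_GROUP_LABELS",
    "CovariateRangeError",
    "validate_covariates",
    "linear_predictor",
    "predicted_risk",
    "odds_ratios",
    "assign_risk_group",
    "score_cohort",
]

#: Plausibility limits for covariates (unit: years, g/l, fl).  Real referral
#: cohorts contain extreme but genuine values (e.g. an MCV of 32 fl), so
#: violations warn by default and only raise under ``strict=True``.
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "age": (16.0, 120.0),
    "hb": (0.0, 250.0),
    "mcv": (20.0, 150.0),
}

RISK_GROUP_LABELS: tuple[str, ...] = (
    "very_low",
    "low",
    "moderate",
    "high",
    "very_high",
)


class CovariateRangeError(ValueError):
    """A covariate lies outside its plausible range (strict mode only)."""


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept and the four predictor coefficients of the logistic score.

    Coefficients are log-odds ratios per unit of the predictor: per male for
    sex, per year for age, per fl for MCV and per g/l for Hb.
    """

    intercept: float
    beta_sex: float
    beta_age: float
    beta_mcv: float
    beta_hb: float
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("intercept", "beta_sex", "beta_age", "beta_mcv", "beta_hb"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"coefficient {name!r} must be finite, got {value!r}")

    def as_array(self) -> np.ndarray:
        """Coefficients in the order (intercept, sex, age, mcv, hb)."""
        return np.array(
            [self.intercept, self.beta_sex, self.beta_age, self.beta_mcv, self.beta_hb]
        )


COEFFICIENT_PRESETS: dict[str, CoefficientSet] = {
    "penalised_printed": CoefficientSet(
        -1.84, 0.89, 0.05, -0.03, -0.06, label="penalised_printed"
    ),
    "penalised_or_consistent": CoefficientSet(
        -1.84, 0.89, 0.05, -0.03, -0.03, label="penalised_or_consistent"
    ),
    "full_model": CoefficientSet(-1.84, 0.94, 0.06, -0.03, -0.03, label="full_model"),
}

DEFAULT_PRESET = "penalised_or_consistent"


def get_coefficients(preset: str = DEFAULT_PRESET) -> CoefficientSet:
    """Return a bundled coefficient preset by name."""
    try:
        return COEFFICIENT_PRESETS[preset]
    except KeyError:
        known = ", ".join(sorted(COEFFICIENT_PRESETS))
        raise KeyError(f"unknown coefficient preset {preset!r}; known presets: {known}")


def coefficients_from_config(path: str | Path, label: str) -> CoefficientSet:
    """Load a coefficient set from a YAML config file.

    The file maps preset labels to the five named coefficients::

        my_refit:
          intercept: -1.9
          beta_sex: 0.8
          beta_age: 0.05
          beta_mcv: -0.03
          beta_hb: -0.03
    """
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or label not in config:
        raise KeyError(f"preset {label!r} not found in {path}")
    entry = config[label]
    required = {"intercept", "beta_sex", "beta_age", "beta_mcv", "beta_hb"}
    missing = required - set(entry)
    if missing:
        raise ValueError(f"preset {label!r} is missing fields: {sorted(missing)}")
    return CoefficientSet(
        intercept=float(entry["intercept"]),
        beta_sex=float(entry["beta_sex"]),
        beta_age=float(entry["beta_age"]),
        beta_mcv=float(entry["beta_mcv"]),
        beta_hb=float(entry["beta_hb"]),
        label=label,
    )


@dataclass(frozen=True)
class RiskGroupScheme:
    """Four ascending probability cut-offs defining five named risk groups.

    Group intervals are left-open and right-closed: a risk exactly equal to a
    cut-off belongs to the lower group, so each cut-off is the highest
    predicted risk inside its group.
    """

    cutoffs: tuple[float, float, float, float]
    labels: tuple[str, ...] = RISK_GROUP_LABELS
    name: str = "custom"

    def __post_init__(self) -> None:
        c = self.cutoffs
        if len(c) != 4:
            raise ValueError("a risk-group scheme needs exactly four cut-offs")
        if not (0.0 < c[0] < c[1] < c[2] < c[3] < 1.0):
            raise ValueError(
                f"cut-offs must be strictly ascending within (0, 1), got {c}"
            )
        if len(self.labels) != 5:
            raise ValueError("a four-cut-off scheme defines exactly five groups")


#: The externally validated scheme: cut-offs 1.18%, 2.16%, 4.24% and 7.97%,
#: derived on the development (Dorset) cohort from the quartiles of the PPV
#: distribution (see :mod:`idiomval.stratification`).
PUBLISHED_SCHEME = RiskGroupScheme(
    cutoffs=(0.0118, 0.0216, 0.0424, 0.0797), name="published"
)


def _as_arrays(cohort) -> dict[str, np.ndarray]:
    """Pull sex/age/hb/mcv out of a DataFrame, mapping or record."""
    out = {}
    for field in ("sex", "age", "hb", "mcv"):
        try:
            out[field] = np.asarray(cohort[field], dtype=float)
        except (KeyError, IndexError, TypeError):
            value = getattr(cohort, field, None)
            if value is None:
                raise KeyError(f"cohort input is missing required field {field!r}")
            out[field] = np.asarray(value, dtype=float)
    return out


def validate_covariates(cohort, *, strict: bool = False) -> None:
    """Check covariates against plausibility ranges and the sex coding.

    Out-of-range values emit a :class:`UserWarning` naming the field, or
    raise :class:`CovariateRangeError` when ``strict`` is true.  Non-finite
    values and sex codes outside {0, 1} are always errors.
    """
    arrays = _as_arrays(cohort)
    for field, values in arrays.items():
        if not np.all(np.isfinite(values)):
            raise ValueError(f"field {field!r} contains non-finite values")
    sex = arrays["sex"]
    if not np.all(np.isin(sex, (0.0, 1.0))):
        raise ValueError("field 'sex' must be coded 0 (female) / 1 (male)")
    for field, (lo, hi) in COVARIATE_RANGES.items():
        values = arrays[field]
        bad = int(np.sum((values < lo) | (values > hi)))
        if bad:
            message = (
                f"field {field!r}: {bad} value(s) outside the plausible "
                f"range [{lo:g}, {hi:g}]"
            )
            if strict:
                raise CovariateRangeError(message)
            warnings.warn(message, stacklevel=2)


def linear_predictor(cohort, coef: CoefficientSet | None = None):
    """Evaluate the score's linear predictor (log-odds of GI malignancy).

    ``cohort`` may be a :class:`pandas.DataFrame`, a mapping of arrays, or any
    object exposing ``sex``/``age``/``hb``/``mcv``.  Returns a float for
    scalar input, else an ndarray.
    """
    if coef is None:
        coef = get_coefficients()
    a = _as_arrays(cohort)
    lp = (
        coef.intercept
        + coef.beta_sex * a["sex"]
        + coef.beta_age * a["age"]
        + coef.beta_mcv * a["mcv"]
        + coef.beta_hb * a["hb"]
    )
    return float(lp) if np.ndim(lp) == 0 else lp


def predicted_risk(cohort, coef: CoefficientSet | None = None):
    """Predicted probability of GI malignancy: expit of the linear predictor."""
    lp = linear_predictor(cohort, coef)
    risk = expit(lp)
    return float(risk) if np.ndim(risk) == 0 else risk


def odds_ratios(coef: CoefficientSet) -> dict[str, dict[str, float]]:
    """Per-predictor odds ratios with the clinical direction convention.

    Every predictor reports ``or_per_unit_increase`` = exp(beta).  Predictors
    with negative coefficients (Hb, MCV in all presets) additionally report
    ``or_per_unit_reduction`` = exp(-beta), the "per g/l reduction" / "per fl
    reduction" form in which falling values raise risk.  Values are returned
    unrounded; round only when formatting a report.
    """
    betas = {
        "sex": coef.beta_sex,
        "age": coef.beta_age,
        "mcv": coef.beta_mcv,
        "hb": coef.beta_hb,
    }
    table: dict[str, dict[str, float]] = {}
    for name, beta in betas.items():
        entry = {"beta": beta, "or_per_unit_increase": float(np.exp(beta))}
        if beta < 0:
            entry["or_per_unit_reduction"] = float(np.exp(-beta))
        table[name] = entry
    return table


def assign_risk_group(risk, scheme: RiskGroupScheme = PUBLISHED_SCHEME):
    """Map predicted risk(s) to the scheme's five group labels.

    Intervals are (c_{k-1}, c_k]: a risk equal to a cut-off falls in the
    lower group.  Risks must lie strictly inside (0, 1).
    """
    arr = np.asarray(risk, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("risks must lie strictly within (0, 1)")
    idx = np.searchsorted(np.asarray(scheme.cutoffs), arr, side="left")
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    if np.ndim(risk) == 0:
        return str(labels if np.ndim(labels) == 0 else labels.item())
    return labels


def score_cohort(
    cohort,
    coef: CoefficientSet | None = None,
    scheme: RiskGroupScheme = PUBLISHED_SCHEME,
    *,
    strict: bool = False,
):
    """Score a cohort table: linear predictor, risk and risk group per patient.

    Returns a :class:`pandas.DataFrame` with columns ``linear_predictor``,
    ``risk`` and ``risk_group``, indexed like the input when it is a
    DataFrame.
    """
    import pandas as pd

    if coef is None:
        coef = get_coefficients()
    validate_covariates(cohort, strict=strict)
    lp = np.atleast_1d(linear_predictor(cohort, coef))
    risk = expit(lp)
    group = assign_risk_group(risk, scheme)
    index = cohort.index if hasattr(cohort, "index") else None
    return pd.DataFrame(
        {"linear_predictor": lp, "risk": risk, "risk_group": group}, index=index
    )
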