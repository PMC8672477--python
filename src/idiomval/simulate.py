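"""Synthetic IDA referral cohorts with a known outcome-generating process.

Patient-level data behind the IDIOM development and validation cohorts are
not publicly deposited, so this module generates stand-in cohorts that
reproduce the published summary structure of the three study sites:

==========  =====  =====  ===============  ==============  ==============  ==========
preset          n   male  age (med,min,max)  Hb g/l          MCV fl         prevalence
==========  =====  =====  ===============  ==============  ==============  ==========
dorset       2390   0.36   71 (16, 96)      104 (32, 159)    80 (53, 112)      8.4%
oxford       1117   0.40   74 (22, 97)       91 (29, 129)    81 (55, 125)      7.7%
sheffield     474   0.48   69 (18, 93)      104 (54, 152)    80 (32, 104)      7.6%
==========  =====  =====  ===============  ==============  ==============  ==========

Continuous covariates are drawn from a truncated normal located at the
published median with scale (max - min)/6, truncated to [min, max]; sex is
Bernoulli(male fraction); covariates are independent by default (no joint
structure is published) with an optional Gaussian-copula hook for
sensitivity studies.  Outcomes come from the logistic score itself in one
of three modes:

``from_model``        y ~ Bernoulli(expit(LP)) — a perfectly calibrated world.
``distorted``         y ~ Bernoulli(expit(a_true + b_true * LP)) — injected
                      miscalibration with known intercept/slope.
``fixed_prevalence``  ``from_model`` after a root-found intercept shift so
                      the expected event rate matches a target (the presets
                      target the published prevalence).

All draws derive from one master seed through named substreams, so adding a
variable to the generator does not perturb the draws of existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .model import CoefficientSet, get_coefficients, linear_predictor

__all__ = [
    "CovariateSpec",
    "OutcomeMode",
    "CohortSpec",
    "COHORT_PRESETS",
    "cohort_preset",
    "generate_cohort",
    "shift_intercept_for_prevalence",
]


@dataclass(frozen=True)
class CovariateSpec:
    """(median, min, max) summary of one continuous covariate."""

    median: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.median < self.max:
            raise ValueError(
                f"need min < median < max, got ({self.median}, {self.min}, {self.max})"
            )


@dataclass(frozen=True)
class OutcomeMode:
    """How outcomes are generated from the linear predictor.

    ``kind`` is one of ``from_model``, ``distorted`` (uses ``a_true`` and
    ``b_true``) or ``fixed_prevalence`` (uses ``prevalence``).
    """

    kind: str = "from_model"
    a_true: float = 0.0
    b_true: float = 1.0
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("from_model", "distorted", "fixed_prevalence"):
            raise ValueError(f"unknown outcome mode {self.kind!r}")
        if self.kind == "fixed_prevalence":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError("fixed_prevalence mode needs prevalence in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    n: int
    male_frac: float
    age_spec: CovariateSpec
    hb_spec: CovariateSpec
    mcv_spec: CovariateSpec
    outcome_mode: OutcomeMode = field(default_factory=OutcomeMode)
    coef: CoefficientSet | None = None  # None -> package default preset
    #: optional rank-correlation matrix over (age, hb, mcv) applied through a
    #: Gaussian copula; None keeps the covariates independent
    rank_corr: np.ndarray | None = None
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not 0.0 <= self.male_frac <= 1.0:
            raise ValueError("male_frac must lie in [0, 1]")
        if self.rank_corr is not None:
            c = np.asarray(self.rank_corr, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError("rank_corr must be a symmetric 3x3 matrix")


COHORT_PRESETS: dict[str, CohortSpec] = {
    "dorset": CohortSpec(
        n=2390,
        male_frac=0.36,
        age_spec=CovariateSpec(71, 16, 96),
        hb_spec=CovariateSpec(104, 32, 159),
        mcv_spec=CovariateSpec(80, 53, 112),
        outcome_mode=OutcomeMode(kind="fixed_prevalence", prevalence=0.084),
        label="dorset",
    ),
    "oxford": CohortSpec(
        n=1117,
        male_frac=0.40,
        age_spec=CovariateSpec(74, 22, 97),
        hb_spec=CovariateSpec(91, 29, 129),
        mcv_spec=CovariateSpec(81, 55, 125),
        outcome_mode=OutcomeMode(kind="fixed_prevalence", prevalence=0.077),
        label="oxford",
    ),
    "sheffield": CohortSpec(
        n=474,
        male_frac=0.48,
        age_spec=CovariateSpec(69, 18, 93),
        hb_spec=CovariateSpec(104, 54, 152),
        mcv_spec=CovariateSpec(80, 32, 104),
        outcome_mode=OutcomeMode(kind="fixed_prevalence", prevalence=0.076),
        label="sheffield",
    ),
}


def cohort_preset(name: str, **overrides) -> CohortSpec:
    """A site preset, optionally with fields overridden (e.g. ``n=50_000`` or
    ``outcome_mode=OutcomeMode("from_model")``)."""
    try:
        spec = COHORT_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(COHORT_PRESETS))
        raise KeyError(f"unknown cohort preset {name!r}; known presets: {known}")
    return replace(spec, **overrides) if overrides else spec


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named draw stream of a master seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _truncnorm_params(spec: CovariateSpec) -> tuple[float, float, float, float]:
    loc, scale = spec.median, (spec.max - spec.min) / 6.0
    return (spec.min - loc) / scale, (spec.max - loc) / scale, loc, scale


def _draw_covariates(spec: CohortSpec, seed: int) -> pd.DataFrame:
    n = spec.n
    if spec.rank_corr is None:
        sex = (_substream(seed, "sex").random(n) < spec.male_frac).astype(int)
        cols = {"sex": sex}
        for name, cov in (
            ("age", spec.age_spec),
            ("hb", spec.hb_spec),
            ("mcv", spec.mcv_spec),
        ):
            a, b, loc, scale = _truncnorm_params(cov)
            cols[name] = truncnorm.rvs(
                a, b, loc=loc, scale=scale, size=n, random_state=_substream(seed, name)
            )
        return pd.DataFrame(cols)
    # Gaussian copula over (age, hb, mcv); sex stays on its own stream
    rng = _substream(seed, "copula")
    z = rng.multivariate_normal(
        np.zeros(3), np.asarray(spec.rank_corr, dtype=float), size=n,
        method="cholesky",
    )
    u = norm.cdf(z)
    cols = {"sex": (_substream(seed, "sex").random(n) < spec.male_frac).astype(int)}
    for j, (name, cov) in enumerate(
        (("age", spec.age_spec), ("hb", spec.hb_spec), ("mcv", spec.mcv_spec))
    ):
        a, b, loc, scale = _truncnorm_params(cov)
        cols[name] = truncnorm.ppf(u[:, j], a, b, loc=loc, scale=scale)
    return pd.DataFrame(cols)


def shift_intercept_for_prevalence(
    coef: CoefficientSet, covariates, prevalence: float, tol: float = 1e-6
) -> float:
    """Intercept shift delta with mean(expit(LP + delta)) = target prevalence.

    Solved by bisection on delta in [-20, 20]; the mean risk is strictly
    increasing in delta, so the root is unique.  Raises if the target is not
    reachable inside the bracket.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    lp = np.asarray(linear_predictor(covariates, coef), dtype=float)

    def mean_risk(delta: float) -> float:
        return float(np.mean(expit(lp + delta)))

    lo, hi = -20.0, 20.0
    if not mean_risk(lo) <= prevalence <= mean_risk(hi):
        raise ValueError(
            f"target prevalence {prevalence} unreachable with shifts in [-20, 20]"
        )
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if mean_risk(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if abs(mean_risk(0.5 * (lo + hi)) - prevalence) < tol:
            break
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Generate one cohort: columns sex, age, hb, mcv, outcome, true_risk.

    ``true_risk`` is the Bernoulli probability each outcome was drawn from —
    the generator's ground truth, available to validation studies but not
    part of the cohort CSV schema.  Identical (spec, seed) pairs produce
    byte-identical cohorts.
    """
    cohort = _draw_covariates(spec, seed)
    coef = spec.coef if spec.coef is not None else get_coefficients()
    lp = np.asarray(linear_predictor(cohort, coef), dtype=float)
    mode = spec.outcome_mode
    if mode.kind == "from_model":
        true_risk = expit(lp)
    elif mode.kind == "distorted":
        true_risk = expit(mode.a_true + mode.b_true * lp)
    else:  # fixed_prevalence
        delta = shift_intercept_for_prevalence(coef, cohort, mode.prevalence)
        true_risk = expit(lp + delta)
    u = _substream(seed, "outcome").random(spec.n)
    cohort["outcome"] = (u < true_risk).astype(int)
    cohort["true_risk"] = true_risk
    return cohort
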