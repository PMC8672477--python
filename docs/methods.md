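# Methods

## The risk model

`idiomval` implements the IDIOM score, a binary logistic model for the
probability of gastrointestinal (GI) malignancy in adults with confirmed
iron deficiency anaemia (IDA):

    logit P(GI malignancy) = b0 + b_sex·sex + b_age·age + b_mcv·MCV + b_hb·Hb

with sex coded 1 = male, age in years, haemoglobin (Hb) in g/l and mean
cell volume (MCV) in fl. Three coefficient presets are bundled
(`penalised_printed`, `penalised_or_consistent`, `full_model`). The two
penalised variants differ only in the Hb coefficient (−0.06 vs −0.03): the
published equation and the published per-g/l odds ratio of 1.03 are mutually
inconsistent, and exp(0.03) = 1.03 together with the reported average
predicted risks (8.5%/5.5%/7.6% across the validation sites) identifies
−0.03 as the value that reproduces the reported behaviour. The package
therefore defaults to the OR-consistent variant and keeps the printed
equation as an explicit alternative rather than silently correcting either.

Predicted risks live in (0, 1) everywhere inside the package; percentages
appear only in the reporting layer (half-up rounding, 2 decimals).

Covariate plausibility ranges (age 16–120 y, Hb 0–250 g/l, MCV 20–150 fl)
warn rather than fail by default, because genuine referral cohorts contain
extreme values (an MCV of 32 fl appears in one site's summary); a strict
flag upgrades them to errors.

## Risk groups and the PPV-quartile derivation

The five risk groups (very low / low / moderate / high / very high) are
defined by four ascending probability cut-offs with left-open, right-closed
intervals: a risk exactly on a cut-off belongs to the lower group. The
externally validated cut-offs are 1.18%, 2.16%, 4.24% and 7.97%.

`derive_ppv_quartile_scheme` reconstructs such a scheme from a development
cohort. Every distinct predicted risk is treated as a strict classification
threshold (investigate iff risk > t) and the positive predictive value (PPV)
above each threshold is computed; the multiset of PPV values is split into
quarters at its quartiles (linear interpolation between order statistics,
"type 7"; the convention is configurable in principle and documented here
because the original description does not state one). Two further
conventions are the package's own, made necessary by properties of real
data:

* **Monotone envelope.** Raw PPV as a function of threshold is not
  monotone: above the bulk of the cohort each PPV is estimated from a
  handful of patients and collapses towards 0 or 1, scattering extreme
  thresholds into the lowest PPV quarter. "The highest threshold in each
  PPV quarter" is therefore taken along the running maximum of PPV over
  ascending thresholds, which maps each quarter to a contiguous threshold
  prefix and guarantees ascending cut-offs whenever the quarters are
  non-empty.
* **NPV floor.** The first cut-off is the highest threshold with a negative
  predictive value of exactly 100% — no event at or below it — so the
  very-low group is event-free on the derivation data by construction.
  Perfectly separated data degenerate (the event-free region swallows the
  whole first quarter) and raise a diagnostic rather than returning a
  collapsed scheme; `npv_floor_threshold` is exposed separately for such
  cohorts.

Classification is strict (`risk > threshold`) throughout the package, which
makes each cut-off the highest predicted risk inside its group and matches
the interval convention above.

## Discrimination

The C-statistic is computed in Mann–Whitney form (ties count ½) via
midranks, and independently as the trapezoidal area under the ROC curve
built over distinct thresholds only; the two agree to 1e−10 and are tested
against full pair enumeration. The default confidence interval is DeLong's
asymptotic method (clipped to [0, 1]); the original analysis does not state
its CI method, so this is a choice, with a seeded percentile bootstrap
available for small samples. The Gmean operating point maximises
√(sensitivity × specificity) over distinct thresholds, ties resolved toward
the lower threshold (higher sensitivity).

## Calibration hierarchy

* **Mean calibration**: observed event rate vs mean predicted risk,
  reported as O/E ratio and as the signed relative difference
  100·(mean predicted − observed)/observed; the two satisfy
  O/E = 1/(1 + diff/100) identically.
* **Weak calibration**: intercept from an intercept-only logistic fit with
  the linear predictor as fixed offset (target 0; negative ⇒ the model
  overestimates), slope from a free-intercept fit on the linear predictor
  (target 1; < 1 ⇒ predictions too extreme). Wald 95% intervals (the CI
  method is unstated in the source analysis). The logistic engine is an
  in-module IRLS (Newton) solver: convergence at max |score| < 1e−8 within
  100 iterations, standard errors from the inverse observed information,
  explicit errors for non-convergence and for complete or quasi-complete
  separation (detected as diverging coefficients or exploding standard
  errors after score convergence — the score also vanishes when fitted
  probabilities saturate along a separating direction).
* **Moderate calibration**: a flexible curve from degree-1 locally weighted
  regression (loess) of the 0/1 outcome on predicted risk — tricube weights
  over the nearest ⌈span·n⌉ points, span 0.75 by default, no robustness
  iterations (none are described in the source methodology), evaluated on
  100 equally spaced points over the observed risk range and clipped to
  [0, 1]. Ties at a grid point fall back to the local mean.
* **Risk-group calibration**: mean predicted vs observed event fraction per
  scheme group. The "fifths" are the five predefined cut-off groups, not
  population quintiles. Zero-event groups are reported with a flag, not an
  error — the very-low group is expected to be event-free.

## Decision analysis

At risk threshold R (= C/(C+B) for investigation cost C and benefit B), the
standardised net benefit of "investigate iff risk > R" against an
investigate-all standard of care is

    sNB(R) = TNR_R − (ρ/(1−ρ)) · ((1−R)/R) · FNR_R

with ρ the prevalence. Reference strategies: investigate-all has
TNR = FNR = 0 (sNB ≡ 0); investigate-no-one has TNR = FNR = 1, so its curve
crosses zero exactly at R = ρ. The default grid is 0.005–0.30 in steps of
0.005, wide enough to bracket clinically debated thresholds; the threshold
of superiority is the largest grid point where the model's sNB is at least
both references'. Clinical impact restates the policy per 1000 patients
(low-risk = risk ≤ R, and true negatives among them) with percentile
bootstrap CIs (B = 1000, seeded; the bootstrap flavour is unstated in the
source, percentile chosen for simplicity and boundedness). 100·sNB can be
read as avoided unnecessary investigations per 100 on the standardised
scale; the package labels it as such rather than asserting any other
denominator convention.

## Synthetic cohorts

Patient-level data for the three study sites are not deposited, so the
generator emulates their published summary structure: sex ~
Bernoulli(male fraction); age, Hb and MCV from truncated normals located at
the published median with scale (max − min)/6, truncated to [min, max].
Matching only median/min/max is a deliberate simplification — skewness and
covariate correlations (e.g. Hb–MCV in IDA) are not published and are not
emulated; an optional Gaussian-copula hook accepts a rank-correlation
matrix for sensitivity studies. Outcomes are drawn from the score itself:
`from_model` (perfectly calibrated), `distorted` (known intercept/slope
miscalibration injected on the logit scale) or `fixed_prevalence`
(bisection-found intercept shift matching a target event rate to 1e−6; the
site presets target the published prevalences of 8.4/7.7/7.6%, since the
unshifted score on the published covariate summaries yields a mean risk of
only ≈ 4–5%). One master seed feeds named substreams (SHA-256-derived child
seeds per variable), so adding a draw stream never perturbs existing ones
and cohorts are byte-identical under a fixed (spec, seed) pair.

Consequently, passing tests demonstrate parameter recovery and internal
consistency of the pipeline under the score's own data-generating process
at the published cohort sizes — they cannot certify performance on real
referral data, where covariates correlate, distributions are skewed, and
the outcome process is not the model.

## Problem sizes used in tests

Asymptotic checks (weak-calibration recovery, intercept recovery, group
calibration gaps, flexible-curve accuracy) run at n = 50,000; consistency
contrasts use n = 2,000 vs 50,000 over 20 seeds; scheme derivation and
decision-curve properties use development-size cohorts (n = 2,390) or
n = 10,000. Small-sample oracles (grid-search likelihood, pair enumeration,
brute-force confusion counts) run on 4–30-record instances, 300–1,000
instances per property.

## Known limitations

* The printed cut-offs, AUCs, calibration intercepts/slopes and superiority
  thresholds of the original study are not recomputable without the real
  site data; the package reproduces exactly the quantities that follow from
  printed inputs and validates everything else by construction on synthetic
  cohorts.
* The loess smoother is a plain tricube local-linear fit; no robustness
  iterations or adaptive spans.
* DeLong CIs are asymptotic; for very few events prefer the bootstrap
  option.
* The quantile convention and the monotone-envelope resolution in the
  scheme derivation are package choices where the original description is
  silent; alternative conventions would shift derived cut-offs slightly.
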