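import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from idiomval.model import (
    COEFFICIENT_PRESETS,
    PUBLISHED_SCHEME,
    CoefficientSet,
    CovariateRangeError,
    RiskGroupScheme,
    assign_risk_group,
    coefficients_from_config,
    get_coefficients,
    linear_predictor,
    odds_ratios,
    predicted_risk,
    score_cohort,
    validate_covariates,
)

RECORD = {"sex": 1, "age": 70, "hb": 100, "mcv": 80}


@pytest.mark.parametrize(
    "preset, expected",
    [
        ("penalised_printed", (-1.84, 0.89, 0.05, -0.03, -0.06)),
        ("penalised_or_consistent", (-1.84, 0.89, 0.05, -0.03, -0.03)),
        ("full_model", (-1.84, 0.94, 0.06, -0.03, -0.03)),
    ],
)
def test_preset_coefficients(preset, expected):
    coef = get_coefficients(preset)
    assert tuple(coef.as_array()) == expected


def test_default_preset_is_or_consistent():
    assert get_coefficients().label == "penalised_or_consistent"


@pytest.mark.parametrize(
    "preset, expected_lp",
    [("penalised_or_consistent", -2.85), ("penalised_printed", -5.85)],
)
def test_linear_predictor_hand_evaluation(preset, expected_lp):
    """A 70-year-old man with Hb 100 g/l and MCV 80 fl, evaluated by hand."""
    lp = linear_predictor(RECORD, get_coefficients(preset))
    assert lp == pytest.approx(expected_lp, abs=1e-12)


def test_linear_predictor_additive_identity():
    zero = CoefficientSet(0.0, 0.0, 0.0, 0.0, 0.0)
    assert linear_predictor(RECORD, zero) == 0.0
    assert predicted_risk(RECORD, zero) == 0.5


def test_predicted_risk_hand_evaluation():
    risk = predicted_risk(RECORD, get_coefficients("penalised_or_consistent"))
    assert risk == pytest.approx(0.05468131721594076, abs=1e-12)


def test_risk_direction_of_effects():
    """Risk rises with age and male sex, falls with higher Hb and MCV."""
    coef = get_coefficients()
    base = predicted_risk(RECORD, coef)
    assert predicted_risk({**RECORD, "hb": 90}, coef) > base
    assert predicted_risk({**RECORD, "mcv": 90}, coef) < base
    assert predicted_risk({**RECORD, "age": 80}, coef) > base
    assert predicted_risk({**RECORD, "sex": 0}, coef) < base


def test_scoring_is_deterministic():
    cohort = pd.DataFrame(
        {"sex": [1, 0], "age": [70, 55], "hb": [100, 120], "mcv": [80, 90]}
    )
    a = score_cohort(cohort)
    b = score_cohort(cohort)
    assert (a == b).all().all()


def test_odds_ratios_match_published_values():
    table = odds_ratios(get_coefficients("penalised_or_consistent"))
    assert round(table["sex"]["or_per_unit_increase"], 2) == 2.44
    assert round(table["age"]["or_per_unit_increase"], 2) == 1.05
    assert round(table["mcv"]["or_per_unit_reduction"], 2) == 1.03
    assert round(table["hb"]["or_per_unit_reduction"], 2) == 1.03


def test_odds_ratio_reduction_is_reciprocal():
    table = odds_ratios(get_coefficients("penalised_printed"))
    for entry in table.values():
        if "or_per_unit_reduction" in entry:
            product = entry["or_per_unit_increase"] * entry["or_per_unit_reduction"]
            assert product == pytest.approx(1.0, abs=1e-14)


def test_zero_beta_gives_unit_odds_ratio():
    table = odds_ratios(CoefficientSet(0.0, 0.0, 0.0, 0.0, 0.0))
    assert table["sex"]["or_per_unit_increase"] == 1.0


@pytest.mark.parametrize(
    "risk, expected",
    [
        (0.0118, "very_low"),  # boundary risks belong to the lower group
        (0.0119, "low"),
        (0.0547, "high"),
        (0.0797, "high"),
        (0.25, "very_high"),
        (0.001, "very_low"),
    ],
)
def test_assign_risk_group_published_scheme(risk, expected):
    assert assign_risk_group(risk, PUBLISHED_SCHEME) == expected


@given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
def test_group_assignment_partitions_unit_interval(risk):
    label = assign_risk_group(risk, PUBLISHED_SCHEME)
    assert label in PUBLISHED_SCHEME.labels


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
def test_assign_risk_group_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        assign_risk_group(bad, PUBLISHED_SCHEME)


def test_scheme_requires_ascending_cutoffs():
    with pytest.raises(ValueError):
        RiskGroupScheme(cutoffs=(0.05, 0.02, 0.1, 0.2))


def test_covariate_ranges_warn_by_default_and_raise_when_strict():
    cohort = {"sex": [1], "age": [130], "hb": [100], "mcv": [80]}
    with pytest.warns(UserWarning, match="age"):
        validate_covariates(cohort)
    with pytest.raises(CovariateRangeError, match="age"):
        validate_covariates(cohort, strict=True)


def test_sex_coding_must_be_binary():
    with pytest.raises(ValueError, match="sex"):
        validate_covariates({"sex": [2], "age": [70], "hb": [100], "mcv": [80]})


def test_coefficients_loadable_from_config(tmp_path):
    path = tmp_path / "coef.yaml"
    entry = dict(intercept=-1.9, beta_sex=0.8, beta_age=0.05, beta_mcv=-0.03, beta_hb=-0.02)
    path.write_text(yaml.safe_dump({"refit": entry}))
    coef = coefficients_from_config(path, "refit")
    assert coef.label == "refit"
    assert coef.beta_hb == -0.02
    with pytest.raises(KeyError):
        coefficients_from_config(path, "missing")


def test_nonfinite_coefficients_rejected():
    with pytest.raises(ValueError):
        CoefficientSet(float("nan"), 0.0, 0.0, 0.0, 0.0)
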