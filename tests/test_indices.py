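"""Fasting index formulas: worked values, algebraic identities, monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clampval import (
    bmi_category,
    convert_glucose,
    fasting_indices,
    firi,
    friedewald_ldl,
    gi_ratio,
    homa_ir,
    quicki,
    SubjectRecord,
)
from clampval.exceptions import DomainError, UnitsError, ValidityError

pos = st.floats(min_value=0.5, max_value=50.0, allow_nan=False)


@pytest.mark.parametrize(
    "func,args,expected",
    [
        (homa_ir, (4.5, 5.0), 1.0),
        (homa_ir, (22.5, 1.0), 1.0),
        (homa_ir, (4.56, 4.66), 4.56 * 4.66 / 22.5),
        (firi, (4.5, 5.0), 0.9),
        (firi, (5.0, 5.0), 1.0),
        (firi, (4.93, 8.95), 4.93 * 8.95 / 25.0),
        (quicki, (100.0, 10.0), 1.0 / 3.0),
        (quicki, (10.0, 1.0), 1.0),
        (quicki, (82.2, 4.66), 1.0 / (math.log10(4.66) + math.log10(82.2))),
        (gi_ratio, (100.0, 10.0), 10.0),
        (gi_ratio, (82.2, 4.66), 82.2 / 4.66),
        (friedewald_ldl, (160.0, 48.0, 50.0), 102.0),
        (friedewald_ldl, (275.0, 70.0, 71.0), 190.8),
        (friedewald_ldl, (100.0, 100.0, 0.0), 0.0),
    ],
)
def test_worked_examples(func, args, expected):
    assert func(*args) == pytest.approx(expected, rel=1e-9)


def test_gi_ratio_mmol_units():
    assert gi_ratio(5.55, 10.0, glucose_units="mmol/L") == pytest.approx(0.555)
    with pytest.raises(UnitsError):
        gi_ratio(5.55, 10.0, glucose_units="g/L")


@settings(max_examples=100, deadline=None)
@given(g=pos, i=pos)
def test_firi_is_nine_tenths_homa(g, i):
    assert firi(g, i) == pytest.approx(0.9 * homa_ir(g, i), rel=1e-12)


@settings(max_examples=50, deadline=None)
@given(g=pos, i=pos, dg=st.floats(min_value=0.01, max_value=5.0))
def test_monotonicity(g, i, dg):
    assert homa_ir(g + dg, i) > homa_ir(g, i)
    assert firi(g, i + dg) > firi(g, i)
    g_mg = g * 20 + 40  # keep QUICKI denominator positive
    assert quicki(g_mg + dg, i + 1) < quicki(g_mg, i + 1)
    assert gi_ratio(g + dg, i) > gi_ratio(g, i)
    assert gi_ratio(g, i + dg) < gi_ratio(g, i)


def test_friedewald_linearity_on_random_cohort(rng):
    tc = rng.uniform(120, 280, size=200)
    hdl = rng.uniform(30, 80, size=200)
    tg = rng.uniform(40, 200, size=200)
    per_subject = np.array([friedewald_ldl(a, b, c) for a, b, c in zip(tc, hdl, tg)])
    assert per_subject.mean() == pytest.approx(
        friedewald_ldl(tc.mean(), hdl.mean(), tg.mean()), rel=1e-10
    )


def test_friedewald_validity_and_warning():
    with pytest.raises(ValidityError):
        friedewald_ldl(200, 50, 401)
    with pytest.warns(UserWarning):
        assert friedewald_ldl(100, 95, 100) == pytest.approx(-15.0)


@pytest.mark.parametrize("func", [homa_ir, firi, quicki, gi_ratio])
def test_domain_errors_on_nonpositive(func):
    with pytest.raises(DomainError):
        func(0.0, 5.0)
    with pytest.raises(DomainError):
        func(5.0, -1.0)
    with pytest.raises(DomainError):
        func(None, 5.0)


def test_quicki_log_base_options():
    v_e = quicki(82.2, 4.66, log_base=math.e)
    assert v_e == pytest.approx(1.0 / (math.log(4.66) + math.log(82.2)))
    with pytest.raises(UnitsError):
        quicki(82.2, 4.66, log_base=2)


@settings(max_examples=50, deadline=None)
@given(x=st.floats(min_value=0.0, max_value=1000.0))
def test_glucose_conversion_round_trip(x):
    back = convert_glucose(convert_glucose(x, "mg/dL", "mmol/L"), "mmol/L", "mg/dL")
    assert back == pytest.approx(x, rel=1e-9, abs=1e-12)


def test_glucose_conversion_values():
    assert convert_glucose(0, "mg/dL", "mmol/L") == 0
    assert convert_glucose(100, "mg/dL", "mmol/L") == pytest.approx(100 / 18.016)
    assert convert_glucose(7.5, "mmol/L", "mmol/L") == 7.5
    with pytest.raises(UnitsError):
        convert_glucose(1.0, "mg/dL", "g/L")


@pytest.mark.parametrize(
    "bmi,expected",
    [(24.9, "lean"), (25.0, "overweight"), (29.99, "overweight"), (30.0, "obese"), (18.0, "lean")],
)
def test_bmi_category_bounds(bmi, expected):
    assert bmi_category(bmi) == expected


def test_bmi_category_domain():
    with pytest.raises(DomainError):
        bmi_category(0)


def test_fasting_indices_bundle():
    rec = SubjectRecord(subject_id="x", sex="M", fasting_glucose=4.56, fasting_insulin=4.66)
    fi = fasting_indices(rec)
    assert fi.homa_ir == pytest.approx(4.56 * 4.66 / 22.5)
    assert fi.firi == pytest.approx(0.9 * fi.homa_ir)
    g_mg = 4.56 * 18.016
    assert fi.quicki == pytest.approx(1.0 / (math.log10(4.66) + math.log10(g_mg)))
    assert fi.gi_ratio == pytest.approx(g_mg / 4.66)


def test_subject_record_consistency_checks():
    rec = SubjectRecord(subject_id="a", sex="F", height=160.0, weight=64.0)
    assert rec.bmi == pytest.approx(25.0)
    rec.validate_consistency()
    bad = SubjectRecord(subject_id="b", sex="F", height=160.0, weight=64.0, bmi=30.0)
    with pytest.raises(DomainError):
        bad.validate_consistency()
    with pytest.raises(DomainError):
        SubjectRecord(subject_id="c", sex="F", weight=-1.0)
    diabetic = SubjectRecord(subject_id="d", sex="M", fasting_glucose=7.2)
    with pytest.raises(DomainError):
        diabetic.validate_consistency()
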