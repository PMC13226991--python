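"""Quadratic calibration: fitting, prediction, inversion, LOD/LOQ, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from platecal import (
    DegenerateDataError,
    NumericalError,
    PolynomialCurve,
    RangeError,
    StandardPoint,
    fit_second_order,
    invert_curve,
    lod_loq,
    mean_curve,
    mean_lod_loq,
    plate_lod_loq,
    predict_area,
)
from platecal.calibration import low_level_se_slope, rescale_curve

from conftest import WORKING_LEVELS, make_standards, quadratic


def curve(a2, a1, a0, rng=(0.0, 10.0)):
    return PolynomialCurve(a2=a2, a1=a1, a0=a0, r_squared=1.0, conc_range=rng)


# ---------------------------------------------------------------------------
# fitting


def test_exact_quadratic_is_interpolated():
    pts = [StandardPoint(str(x), x, 2 * x * x + 3 * x + 1) for x in range(1, 6)]
    c = fit_second_order(pts)
    assert (c.a2, c.a1, c.a0) == pytest.approx((2, 3, 1), rel=1e-9)
    assert c.r_squared == pytest.approx(1.0, abs=1e-12)
    assert c.conc_range == (1, 5)
    assert c.monotone


def test_refit_recovers_published_plate1_equation(plate1_curve_fn):
    """Points generated from the plate-1 equation refit to its coefficients."""
    pts = make_standards(plate1_curve_fn, WORKING_LEVELS)
    c = fit_second_order(pts)
    assert c.a2 == pytest.approx(-3e-09, rel=1e-6)
    assert c.a1 == pytest.approx(2e-05, rel=1e-6)
    assert c.a0 == pytest.approx(0.0005, rel=1e-6)
    assert c.r_squared == pytest.approx(1.0, abs=1e-9)


def test_collinear_points_give_degenerate_quadratic():
    pts = [StandardPoint(str(x), x, 2.0 * x) for x in (1.0, 2.0, 3.0)]
    c = fit_second_order(pts)
    assert abs(c.a2) < 1e-9
    assert c.a1 == pytest.approx(2.0, rel=1e-6)
    assert c.r_squared == pytest.approx(1.0, abs=1e-12)


def test_duplicated_concentrations_only_rejected():
    pts = [StandardPoint("a", 1, 0.1), StandardPoint("b", 1, 0.11),
           StandardPoint("c", 2, 0.2), StandardPoint("d", 2, 0.21)]
    with pytest.raises(DegenerateDataError, match="distinct"):
        fit_second_order(pts)


def test_non_monotone_fit_is_flagged_not_fatal():
    # response peaks inside the range: vertex of -(x-5)^2+30 at x=5
    pts = [StandardPoint(str(x), x, -(x - 5.0) ** 2 + 30.0)
           for x in (1, 3, 5, 7, 9)]
    c = fit_second_order(pts)
    assert not c.monotone


@settings(derandomize=True, max_examples=50)
@given(k=st.floats(0.1, 50.0))
def test_fit_is_scale_equivariant(k):
    f = quadratic(-3e-9, 2e-5, 5e-4)
    base = fit_second_order(make_standards(f, WORKING_LEVELS))
    scaled = fit_second_order(make_standards(f, WORKING_LEVELS, scale=k))
    assert scaled.a2 == pytest.approx(base.a2 * k, rel=1e-6, abs=1e-18)
    assert scaled.a1 == pytest.approx(base.a1 * k, rel=1e-6)
    assert scaled.a0 == pytest.approx(base.a0 * k, rel=1e-6, abs=1e-12)
    assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-9)


def test_weighted_fit_option_runs():
    f = quadratic(-3e-9, 2e-5, 5e-4)
    c = fit_second_order(make_standards(f, WORKING_LEVELS), weighting="1/x2")
    assert c.a1 == pytest.approx(2e-5, rel=1e-6)


# ---------------------------------------------------------------------------
# prediction and inversion


def test_predict_linear_case():
    assert predict_area(curve(0, 2, 0), 5.0) == pytest.approx(10.0)


def test_predict_published_plate1_at_500():
    c = curve(-3e-09, 2e-05, 0.0005, rng=(125, 2000))
    assert predict_area(c, 500.0) == pytest.approx(0.00975, rel=1e-12)


def test_predict_refuses_extrapolation_by_default():
    c = curve(-3e-09, 2e-05, 0.0005, rng=(125, 2000))
    with pytest.raises(RangeError):
        predict_area(c, 5000.0)
    # configurable tolerance admits mild extrapolation
    assert predict_area(c, 2100.0, extrapolation_tol=0.1) > 0


def test_invert_linear_case():
    assert invert_curve(curve(0, 2, 0), 10.0) == pytest.approx(5.0)


def test_invert_round_trips_published_plate1():
    c = curve(-3e-09, 2e-05, 0.0005, rng=(125, 2000))
    assert invert_curve(c, 0.00975) == pytest.approx(500.0, rel=1e-9)


def test_invert_out_of_range_area():
    c = curve(-3e-09, 2e-05, 0.0005, rng=(125, 2000))
    with pytest.raises(RangeError):
        invert_curve(c, predict_area(c, 125) * 0.5)


def test_invert_refuses_ambiguous_roots():
    # symmetric hump around the vertex at 5: two roots inside the range
    c = PolynomialCurve(a2=-1.0, a1=10.0, a0=0.0, r_squared=1.0,
                        conc_range=(2.0, 8.0), monotone=False)
    with pytest.raises(NumericalError, match="two in-range roots"):
        invert_curve(c, 16.0)


@st.composite
def monotone_curves_and_conc(draw):
    a1 = draw(st.floats(1e-6, 1e-4))
    hi = draw(st.floats(500, 3000))
    lo = draw(st.floats(10, 100))
    # vertex -a1/(2 a2) outside [lo, hi] => strictly monotone over the range
    a2 = draw(st.floats(-0.8 * a1 / (2 * hi), 0.5 * a1 / hi))
    a0 = draw(st.floats(-1e-3, 1e-3))
    conc = draw(st.floats(lo, hi))
    return curve(a2, a1, a0, rng=(lo, hi)), conc


@settings(derandomize=True, max_examples=200)
@given(monotone_curves_and_conc())
def test_inversion_round_trip_identity(cc):
    """invert(predict(c)) = c to 1e-9 relative across the working range."""
    c, conc = cc
    assert invert_curve(c, predict_area(c, conc)) == pytest.approx(
        conc, rel=1e-9
    )


# ---------------------------------------------------------------------------
# LOD / LOQ


@pytest.mark.parametrize("se, slope, lod, loq", [
    (1.0, 1.0, 3.3, 10.0),
    (0.01, 0.002, 16.5, 50.0),
])
def test_lod_loq_arithmetic(se, slope, lod, loq):
    r = lod_loq(se, slope)
    assert r.lod == pytest.approx(lod)
    assert r.loq == pytest.approx(loq)


@settings(derandomize=True, max_examples=50)
@given(se=st.floats(1e-6, 1.0), slope=st.floats(1e-6, 1.0))
def test_loq_lod_ratio_is_forced(se, slope):
    r = lod_loq(se, slope)
    assert r.loq / r.lod == pytest.approx(10 / 3.3, rel=1e-12)


def test_lod_loq_rejects_bad_slope():
    with pytest.raises(NumericalError):
        lod_loq(0.01, 0.0)


def test_low_level_se_slope_on_perfect_line():
    pts = [StandardPoint(str(x), x, 2e-5 * x) for x in (125, 250, 500, 1000)]
    se, slope = low_level_se_slope(pts)
    assert se == pytest.approx(0.0, abs=1e-12)
    assert slope == pytest.approx(2e-5, rel=1e-9)
    ll = plate_lod_loq(pts)
    assert ll.lod == pytest.approx(0.0, abs=1e-12)


def test_mean_lod_loq():
    singles = [lod_loq(3.0, 0.1), lod_loq(6.0, 0.1)]
    ml, mq = mean_lod_loq(singles)
    assert ml == pytest.approx(np.mean([s.lod for s in singles]))
    assert mq / ml == pytest.approx(10 / 3.3)
    with pytest.raises(DegenerateDataError):
        mean_lod_loq([])


# ---------------------------------------------------------------------------
# mean curve


def test_mean_of_one_curve_is_that_curve():
    c = curve(-3e-9, 2e-5, 5e-4, rng=(125, 2000))
    m = mean_curve([c])
    assert (m.a2, m.a1, m.a0) == (c.a2, c.a1, c.a0)
    assert m.conc_range == c.conc_range


def test_mean_of_two_simple_curves():
    m = mean_curve([curve(0, 1, 0), curve(0, 3, 2)])
    assert (m.a2, m.a1, m.a0) == pytest.approx((0, 2, 1))


def test_mean_a2_of_all_published_curves(fixtures):
    curves = [curve(a2, a1, a0, rng=(125, 2000))
              for a2, a1, a0, _ in fixtures.table2.values()]
    m = mean_curve(curves)
    assert m.a2 == pytest.approx(-89 / 28 * 1e-9, rel=1e-9)
    assert m.conc_range == (125, 2000)


def test_mean_curve_rejects_disjoint_ranges():
    with pytest.raises(NumericalError, match="disjoint"):
        mean_curve([curve(0, 1, 0, rng=(0, 1)), curve(0, 1, 0, rng=(2, 3))])
    with pytest.raises(DegenerateDataError):
        mean_curve([])


def test_rescale_curve_scales_responses():
    c = fit_second_order(
        make_standards(quadratic(-3e-9, 2e-5, 5e-4), WORKING_LEVELS)
    )
    k = rescale_curve(c, 2.0)
    assert k.predict(500.0) == pytest.approx(2 * c.predict(500.0), rel=1e-12)
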