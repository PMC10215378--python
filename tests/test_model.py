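"""Core curve mathematics: evaluation, slope, stationary doses, regimes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from linlogfit import (
    DEGENERATE,
    MONOTONE,
    TWO_POINTS,
    LinLogParams,
    classify_regime,
    linlog_eval,
    linlog_slope,
    stationary_points,
)


def numeric_stationary_points(params, xtol=1e-12):
    """Independent oracle: bracket and bisect the slope's two zeros.

    The slope is positive in both tails and negative at the sigmoid
    midpoint ln(d)/f whenever a dip exists, so each zero can be
    bracketed by stepping outward from the midpoint.
    """
    mid = math.log(params.d) / params.f
    assert linlog_slope(params, mid) < 0
    w = 1.0 / params.f
    lo = mid - w
    while linlog_slope(params, lo) <= 0:
        w *= 2.0
        lo = mid - w
    rmax = brentq(lambda x: linlog_slope(params, x), lo, mid, xtol=xtol)
    w = 1.0 / params.f
    hi = mid + w
    while linlog_slope(params, hi) <= 0:
        w *= 2.0
        hi = mid + w
    rmin = brentq(lambda x: linlog_slope(params, x), mid, hi, xtol=xtol)
    return rmax, rmin


def draw_two_point_params(rng):
    """Random valid parameters guaranteed to have c*f > 4*b."""
    b = float(10.0 ** rng.uniform(-1, 1))
    f = float(10.0 ** rng.uniform(-1, 1))
    rho = float(10.0 ** rng.uniform(math.log10(1.02), math.log10(50.0)))
    c = 4.0 * b * rho / f
    d = float(10.0 ** rng.uniform(0.2, 6.0))
    a = float(rng.uniform(-5, 5))
    return LinLogParams(a=a, b=b, c=c, d=d, f=f)


@pytest.mark.parametrize(
    "params, x, expected",
    [
        (LinLogParams(1, 2, 0, 1, 1), 3.0, 7.0),  # c=0 reduces to the line
        (LinLogParams(0, 1, 10, 100, 1), 0.0, -10.0 / 101.0),
        (LinLogParams(0, 1, 10, 100, 1), 100.0, 90.0),  # asymptote a+bx-c
    ],
)
def test_eval_known_values(params, x, expected):
    assert linlog_eval(params, x) == pytest.approx(expected, abs=1e-9)


def test_eval_vectorized_matches_scalar(ref_params):
    xs = np.linspace(-2, 8, 23)
    vec = linlog_eval(ref_params, xs)
    assert vec.shape == xs.shape
    assert np.allclose(vec, [linlog_eval(ref_params, float(x)) for x in xs])


def test_eval_overflow_safe():
    p = LinLogParams(0, 1, 10, 100, 100.0)
    for x in (-1e4, -100.0, 100.0, 1e4):
        y = linlog_eval(p, x)
        assert math.isfinite(y)
    # deep in the left tail the logistic term vanishes
    assert linlog_eval(p, -1e4) == pytest.approx(-1e4, rel=1e-12)
    # deep in the right tail the full drop c is realised
    assert linlog_eval(p, 1e4) == pytest.approx(1e4 - 10, rel=1e-12)


def test_slope_of_line_is_b():
    p = LinLogParams(3, 2.5, 0, 1, 1)
    for x in (-50.0, 0.0, 7.0, 1e4):
        assert linlog_slope(p, x) == 2.5


def test_slope_at_midpoint_is_b_minus_cf_over_4():
    p = LinLogParams(0, 1, 10, 100, 2.0)
    mid = math.log(p.d) / p.f
    assert linlog_slope(p, mid) == pytest.approx(p.b - p.c * p.f / 4.0, rel=1e-12)


def test_slope_matches_finite_difference(ref_params):
    x, h = 2.0, 1e-6
    fd = (linlog_eval(ref_params, x + h) - linlog_eval(ref_params, x - h)) / (2 * h)
    assert linlog_slope(ref_params, x) == pytest.approx(fd, abs=1e-6)


class TestStationaryPoints:
    def test_two_points_reference(self, ref_params):
        st_pts = stationary_points(ref_params)
        assert st_pts.regime == TWO_POINTS
        # frozen values from the bracketing/bisection oracle
        assert st_pts.rmax == pytest.approx(2.541733117092531, abs=1e-9)
        assert st_pts.rmin == pytest.approx(6.668607254883652, abs=1e-9)
        orx, orn = numeric_stationary_points(ref_params)
        assert st_pts.rmax == pytest.approx(orx, abs=1e-9)
        assert st_pts.rmin == pytest.approx(orn, abs=1e-9)

    def test_monotone_when_dip_too_shallow(self):
        assert stationary_points(LinLogParams(0, 1, 2, 10, 1)).regime == MONOTONE

    def test_degenerate_double_root(self):
        st_pts = stationary_points(LinLogParams(0, 1, 4, 50, 1))
        assert st_pts.regime == DEGENERATE
        assert st_pts.rmax == st_pts.rmin == pytest.approx(math.log(50.0))

    def test_degenerate_tolerance_band(self):
        # a hair away from c*f = 4*b must not produce complex-root garbage
        eps = 1e-12
        st_pts = stationary_points(LinLogParams(0, 1, 4 * (1 + eps), 50, 1))
        assert st_pts.regime == DEGENERATE

    def test_c_zero_is_monotone(self):
        assert stationary_points(LinLogParams(0, 1, 0, 10, 1)).regime == MONOTONE


@pytest.mark.parametrize(
    "params, regime",
    [
        (LinLogParams(0, 1, 10, 100, 1), TWO_POINTS),
        (LinLogParams(0, 1, 2, 10, 1), MONOTONE),
        (LinLogParams(0, 1, 4, 50, 1), DEGENERATE),
    ],
)
def test_classify_regime(params, regime):
    assert classify_regime(params) == regime


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_closed_form_matches_numeric_roots(seed):
    rng = np.random.default_rng(seed)
    p = draw_two_point_params(rng)
    st_pts = stationary_points(p)
    assert st_pts.regime == TWO_POINTS
    orx, orn = numeric_stationary_points(p)
    span = st_pts.rmin - st_pts.rmax + 1.0
    assert abs(st_pts.rmax - orx) < 1e-8 * span
    assert abs(st_pts.rmin - orn) < 1e-8 * span


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_two_point_invariants(seed):
    """Symmetry, ordering and extremality of the stationary doses."""
    rng = np.random.default_rng(seed)
    p = draw_two_point_params(rng)
    st_pts = stationary_points(p)
    mid = 2.0 * math.log(p.d) / p.f
    # u+ * u- = 1/d^2  =>  Rmax + Rmin = 2 ln(d)/f
    assert st_pts.rmax + st_pts.rmin == pytest.approx(mid, rel=1e-9)
    assert st_pts.rmax < st_pts.rmin
    assert linlog_eval(p, st_pts.rmax) > linlog_eval(p, st_pts.rmin)
    inside = 0.5 * (st_pts.rmax + st_pts.rmin)
    assert linlog_slope(p, inside) < 0
    gap = st_pts.rmin - st_pts.rmax
    assert linlog_slope(p, st_pts.rmax - 0.5 * gap) > 0
    assert linlog_slope(p, st_pts.rmin + 0.5 * gap) > 0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_monotone_regime_has_positive_slope(seed):
    rng = np.random.default_rng(seed)
    b = float(10.0 ** rng.uniform(-1, 1))
    f = float(10.0 ** rng.uniform(-1, 1))
    rho = float(rng.uniform(0.05, 0.95))  # c*f < 4*b
    p = LinLogParams(0.0, b, 4.0 * b * rho / f, float(10.0 ** rng.uniform(0.2, 4)), f)
    assert classify_regime(p) == MONOTONE
    mid = math.log(p.d) / p.f
    grid = np.linspace(mid - 50 / f, mid + 50 / f, 501)
    assert np.all(linlog_slope(p, grid) > 0)


def test_c_zero_equals_line_everywhere():
    p = LinLogParams(1.5, 0.7, 0.0, 3.0, 2.0)
    xs = np.linspace(-100, 100, 401)
    assert np.array_equal(linlog_eval(p, xs), 1.5 + 0.7 * xs)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(a=math.nan, b=1, c=1, d=1, f=1), "a"),
        (dict(a=0, b=-1, c=1, d=1, f=1), "b"),
        (dict(a=0, b=1, c=-1, d=1, f=1), "c"),
        (dict(a=0, b=1, c=1, d=0, f=1), "d"),
        (dict(a=0, b=1, c=1, d=1, f=math.inf), "f"),
    ],
)
def test_invalid_params_name_the_field(kwargs, field):
    with pytest.raises(ValueError, match=f"'{field}'"):
        LinLogParams(**kwargs)


def test_nonfinite_dose_rejected(ref_params):
    with pytest.raises(ValueError, match="x"):
        linlog_eval(ref_params, math.nan)
    with pytest.raises(ValueError, match="x"):
        linlog_slope(ref_params, np.array([1.0, math.inf]))
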