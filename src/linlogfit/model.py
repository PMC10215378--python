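"""Exact mathematics of the linear-logistic dose-response model.

The model is

    y(x) = a + b*x - c / (1 + d * exp(-f*x))

a rising line from which a sigmoidal drop is subtracted, producing the
rise-dip-rise shape seen in amino-acid titration studies: the response
(weight gain, nitrogen retention, ...) climbs with intake, dips over an
intermediate dose band, and resumes climbing.  The dip is bracketed by two
stationary doses: ``Rmax``, the dose at which the response is locally
maximised, and ``Rmin``, the larger dose at which it is locally minimised.

Setting the derivative

    y'(x) = b - c*d*f*exp(-f*x) / (1 + d*exp(-f*x))**2

to zero and substituting u = exp(-f*x) gives the quadratic

    b*d**2 * u**2 + (2*b*d - c*d*f) * u + b = 0

whose discriminant (up to a positive factor) is  Δ = c*f*(c*f - 4*b).
When Δ > 0 the two roots

    u± = (c*f - 2*b ± sqrt(Δ)) / (2*b*d)

yield Rmax = -ln(u₊)/f (the smaller dose) and Rmin = -ln(u₋)/f.  Because
u₊*u₋ = 1/d², the two stationary doses always satisfy the exact identity
Rmax + Rmin = 2*ln(d)/f.  When Δ = 0 the curve has a single flat point at
ln(d)/f; when Δ < 0 (the dip is too shallow relative to the line's slope,
c*f < 4*b) the curve is strictly increasing and no stationary dose exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "LinLogParams",
    "StationaryPoints",
    "linlog_eval",
    "linlog_slope",
    "stationary_points",
    "classify_regime",
    "TWO_POINTS",
    "DEGENERATE",
    "MONOTONE",
]

TWO_POINTS = "two_points"
DEGENERATE = "degenerate"
MONOTONE = "monotone"

#: relative tolerance at which c*f == 4*b is declared a double root
DISCRIMINANT_RTOL = 1e-10


@dataclass(frozen=True)
class LinLogParams:
    """Coefficients of the linear-logistic model.

    Parameters
    ----------
    a : float
        Intercept of the linear component, in response units.
    b : float
        Slope of the linear component, response units per dose unit.
        Must be positive: the underlying trend rises with intake.
    c : float
        Amplitude of the logistic drop, in response units.  ``c = 0``
        degenerates the model to the pure line ``a + b*x``.
    d : float
        Dimensionless logistic offset; the drop is centred at dose
        ``ln(d)/f``.  Must be positive.
    f : float
        Logistic rate, per dose unit.  Must be positive.
    """

    a: float
    b: float
    c: float
    d: float
    f: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "f"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v!r}")
        if self.b <= 0:
            raise ValueError(f"parameter 'b' must be > 0, got {self.b!r}")
        if self.c < 0:
            raise ValueError(f"parameter 'c' must be >= 0, got {self.c!r}")
        if self.d <= 0:
            raise ValueError(f"parameter 'd' must be > 0, got {self.d!r}")
        if self.f <= 0:
            raise ValueError(f"parameter 'f' must be > 0, got {self.f!r}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.f)


@dataclass(frozen=True)
class StationaryPoints:
    """Stationary doses of a linear-logistic curve.

    ``regime`` is one of ``"two_points"`` (Rmax < Rmin, a genuine dip),
    ``"degenerate"`` (a single flat point, rmax == rmin == ln(d)/f) or
    ``"monotone"`` (strictly rising curve; both doses absent).
    """

    regime: str
    rmax: Optional[float] = None
    rmin: Optional[float] = None

    def __post_init__(self) -> None:
        if self.regime not in (TWO_POINTS, DEGENERATE, MONOTONE):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == TWO_POINTS and not self.rmax < self.rmin:  # type: ignore[operator]
            raise ValueError("two_points regime requires rmax < rmin")
        if self.regime == MONOTONE and (self.rmax is not None or self.rmin is not None):
            raise ValueError("monotone regime carries no stationary doses")


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("dose 'x' must be finite")
    return x


def linlog_eval(params: LinLogParams, x):
    """Evaluate the linear-logistic curve at dose(s) ``x``.

    The logistic term ``c / (1 + d*exp(-f*x))`` is computed as
    ``c * expit(f*x - ln d)``, which is overflow-safe for arbitrarily
    large ``|f*x|`` (doses on a percent-of-requirement scale make
    ``f*x`` of order 100 entirely plausible).
    """
    x = _check_x(x)
    a, b, c, d, f = params.as_tuple()
    out = a + b * x - c * expit(f * x - math.log(d))
    return out if out.ndim else float(out)


def linlog_slope(params: LinLogParams, x):
    """First derivative (slope) of the curve at dose(s) ``x``.

    Equal to ``b - c*f*s*(1-s)`` with ``s = expit(f*x - ln d)``; the
    product ``s*(1-s)`` underflows gracefully to 0 in both tails.
    """
    x = _check_x(x)
    a, b, c, d, f = params.as_tuple()
    s = expit(f * x - math.log(d))
    out = b - c * f * s * (1.0 - s)
    return out if out.ndim else float(out)


def stationary_points(params: LinLogParams) -> StationaryPoints:
    """Closed-form stationary doses (Rmax, Rmin) and regime.

    Solves ``b*(1 + d*u)**2 = c*d*f*u`` for ``u = exp(-f*x)``.  With
    ``Δ = c*f*(c*f - 4*b)``:

    * ``Δ > 0`` — two roots ``u± = (c*f - 2*b ± sqrt(Δ)) / (2*b*d)``;
      ``Rmax = -ln(u₊)/f`` (local maximum, the smaller dose) and
      ``Rmin = -ln(u₋)/f`` (local minimum).
    * ``Δ ≈ 0`` (|c*f - 4*b| within ``DISCRIMINANT_RTOL`` relative) —
      a single flat point at ``ln(d)/f``.
    * ``Δ < 0`` or ``c = 0`` — strictly increasing curve, no points.
    """
    _, b, c, d, f = params.as_tuple()
    if c == 0.0:
        return StationaryPoints(MONOTONE)
    cf = c * f
    fourb = 4.0 * b
    if abs(cf - fourb) <= DISCRIMINANT_RTOL * max(cf, fourb):
        x0 = math.log(d) / f
        return StationaryPoints(DEGENERATE, rmax=x0, rmin=x0)
    if cf < fourb:
        return StationaryPoints(MONOTONE)
    sqrt_disc = math.sqrt(cf * (cf - fourb))
    u_plus = (cf - 2.0 * b + sqrt_disc) / (2.0 * b * d)
    u_minus = (cf - 2.0 * b - sqrt_disc) / (2.0 * b * d)
    # cf > 4b > 0 makes both numerators positive; anything else would
    # put exp(-f*x) outside its range and indicates a logic error.
    assert u_plus > 0.0 and u_minus > 0.0
    rmax = -math.log(u_plus) / f
    rmin = -math.log(u_minus) / f
    return StationaryPoints(TWO_POINTS, rmax=rmax, rmin=rmin)


def classify_regime(params: LinLogParams) -> str:
    """Regime label only: ``two_points``, ``degenerate`` or ``monotone``."""
    return stationary_points(params).regime
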