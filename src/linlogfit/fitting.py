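"""Model fitting for titration data.

Fits the linear-logistic model by multi-start nonlinear least squares,
plus the companion candidate models used in requirement estimation:
segmented (linear-plateau) regression, quadratic-plateau, a simple
logistic, and a plain quadratic.  Model selection among candidates is by
AICc, the small-sample-corrected information criterion.

Internally doses are standardised to [0, 1] and responses to [0, 1]
before optimisation, and the linear-logistic sigmoid is parameterised by
its midpoint ``m = ln(d)/f`` with ``b, c, f`` on the log scale; this
enforces the sign convention (rising line, non-negative dip) without
penalties and keeps the problem well conditioned whether doses are
percent-of-diet (~0.5) or percent-of-requirement ratios (~100).
Reported coefficients are always back-transformed to the caller's units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit

from .data import DoseResponseTable
from .model import (
    LinLogParams,
    StationaryPoints,
    linlog_eval,
    stationary_points,
)

__all__ = [
    "LinLogFit",
    "SegmentedFit",
    "QuadPlateauFit",
    "LogisticFit",
    "QuadraticFit",
    "ModelSelection",
    "fit_linlog",
    "fit_segmented",
    "fit_candidates",
    "normalize_dose",
    "nearest_treatment",
    "aicc",
    "CANDIDATE_MODELS",
]

ASCENDING_PLATEAU = "ascending-plateau"
PLATEAU_ASCENDING = "plateau-ascending"

#: number of free mean-model parameters per candidate (variance excluded)
_N_PARAMS = {
    "linear-logistic": 5,
    "logistic": 4,
    "linear-plateau": 3,
    "quadratic-plateau": 3,
    "quadratic": 3,
}

CANDIDATE_MODELS = (
    "linear-logistic",
    "linear-plateau",
    "quadratic-plateau",
    "logistic",
    "quadratic",
)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``k`` counts the mean-model parameters; the residual variance adds
    one.  Returns ``+inf`` when the correction term is undefined
    (n <= k + 2), which simply removes over-parameterised candidates
    from contention on tiny designs.
    """
    k_tot = k + 1
    if n - k_tot - 1 <= 0:
        return math.inf
    # floor rss to keep the log finite on numerically exact fits
    return n * math.log(max(rss, 1e-300) / n) + 2 * k_tot + 2 * k_tot * (k_tot + 1) / (
        n - k_tot - 1
    )


def _r2(rss: float, y: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 1.0 if rss <= 1e-300 else -math.inf
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# linear-logistic fit
# ---------------------------------------------------------------------------


@dataclass
class LinLogFit:
    """Result of a linear-logistic least-squares fit."""

    params: LinLogParams
    stationary: StationaryPoints
    residuals: np.ndarray
    rss: float
    r2: float
    aicc: float
    n_starts_tried: int
    converged: bool
    dose_scale: tuple[float, float]  # (offset, range) of the internal rescaling

    model_name: str = "linear-logistic"
    n_params: int = 5

    def predict(self, x):
        return linlog_eval(self.params, x)


def _check_fittable(data: DoseResponseTable, min_n: int, min_levels: int) -> None:
    if len(data) < min_n:
        raise ValueError(
            f"need at least {min_n} observations, got {len(data)}"
        )
    if data.n_levels < min_levels:
        raise ValueError(
            f"need at least {min_levels} distinct dose levels, got {data.n_levels}"
        )
    if np.ptp(data.response) == 0.0:
        raise ValueError("response is constant; nothing to fit")


def _scaled_xy(data: DoseResponseTable):
    x = data.dose
    y = data.response
    x0, xr = float(x.min()), float(np.ptp(x))
    y0, yr = float(y.min()), float(np.ptp(y))
    return (x - x0) / xr, (y - y0) / yr, (x0, xr), (y0, yr)


def _linlog_theta_residuals(theta, xs, ys):
    a, lb, lc, m, lf = theta
    f = math.exp(lf)
    return a + math.exp(lb) * xs - math.exp(lc) * expit(f * (xs - m)) - ys


def _default_starts(xs: np.ndarray, ys: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid in scaled coordinates.

    The line (a, b) is anchored on the upper third of the dose range,
    where the curve has re-joined its linear trend; the dip amplitude c
    is seeded at 1-3x the largest downward residual from that line; the
    sigmoid midpoint sweeps the interior dose quantiles and the rate f a
    coarse span of plausible transition widths.
    """
    upper = xs >= xs.min() + 2.0 / 3.0 * np.ptp(xs)
    if np.unique(xs[upper]).size >= 2:
        b0, a0 = np.polyfit(xs[upper], ys[upper], 1)
    else:
        b0, a0 = np.polyfit(xs, ys, 1)
    b0 = max(float(b0), 0.05)
    dip = float(np.max(a0 + b0 * xs - ys))
    dip = max(dip, 1e-3)
    mids = np.quantile(np.unique(xs), [0.25, 0.4, 0.5, 0.6, 0.75])
    starts = []
    for cmult in (1.0, 2.0, 3.0):
        for m in mids:
            for f0 in (2.0, 5.0, 10.0):
                starts.append(
                    np.array(
                        [a0, math.log(b0), math.log(cmult * dip), float(m), math.log(f0)]
                    )
                )
    return starts


_THETA_LO = np.array([-1e6, -30.0, -30.0, -3.0, math.log(0.2)])
_THETA_HI = np.array([1e6, 16.0, 16.0, 4.0, math.log(200.0)])


def _theta_from_params(params: LinLogParams, xscale, yscale) -> np.ndarray:
    """Map raw-unit parameters into the scaled internal coordinates."""
    x0, xr = xscale
    y0, yr = yscale
    a, b, c, d, f = params.as_tuple()
    fs = f * xr
    m = (math.log(d) / f - x0) / xr
    bs = b * xr / yr
    as_ = (a + b * x0 - y0) / yr
    cs = c / yr
    theta = np.array(
        [as_, math.log(max(bs, 1e-13)), math.log(max(cs, 1e-13)), m, math.log(fs)]
    )
    return np.clip(theta, _THETA_LO + 1e-9, _THETA_HI - 1e-9)


def _params_from_theta(theta, xscale, yscale) -> LinLogParams:
    x0, xr = xscale
    y0, yr = yscale
    a_s, lb, lc, m, lf = theta
    fs, bs, cs = math.exp(lf), math.exp(lb), math.exp(lc)
    f = fs / xr
    b = bs * yr / xr
    c = cs * yr
    a = y0 + yr * a_s - b * x0
    log_d = f * (x0 + m * xr)
    if log_d > 700.0:
        raise OverflowError(
            "fitted sigmoid offset d = exp(f*midpoint) overflows; the dose "
            "axis has an extreme offset relative to its range"
        )
    return LinLogParams(a=a, b=b, c=c, d=math.exp(log_d), f=f)


def fit_linlog(
    data: DoseResponseTable,
    *,
    collapse_replicates: bool = False,
    start_params: Optional[LinLogParams] = None,
    include_default_starts: bool = True,
) -> LinLogFit:
    """Fit the linear-logistic model by multi-start least squares.

    Parameters
    ----------
    data : DoseResponseTable
        Observations; replicates are fitted individually unless
        ``collapse_replicates`` collapses them to level means first.
    start_params : LinLogParams, optional
        Warm start in raw units.  When given with
        ``include_default_starts=False`` only this start is used — the
        mode used for bootstrap replicates, where the full-data estimate
        is a near-optimal start.
    """
    if collapse_replicates:
        data = data.level_means()
    _check_fittable(data, min_n=5, min_levels=4)
    xs, ys, xscale, yscale = _scaled_xy(data)

    starts: list[np.ndarray] = []
    if start_params is not None:
        starts.append(_theta_from_params(start_params, xscale, yscale))
    if include_default_starts or not starts:
        starts.extend(_default_starts(xs, ys))

    best = None
    best_cost = math.inf
    any_ok = False
    for theta0 in starts:
        try:
            res = least_squares(
                _linlog_theta_residuals,
                np.clip(theta0, _THETA_LO, _THETA_HI),
                args=(xs, ys),
                bounds=(_THETA_LO, _THETA_HI),
                method="trf",
                x_scale="jac",
                ftol=1e-13,
                xtol=1e-13,
                gtol=1e-13,
                max_nfev=400,
            )
        except (ValueError, OverflowError):
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        any_ok = any_ok or res.status > 0
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        raise RuntimeError("every optimisation start failed")

    params = _params_from_theta(best.x, xscale, yscale)
    resid = data.response - linlog_eval(params, data.dose)
    rss = float(resid @ resid)
    n = len(data)
    return LinLogFit(
        params=params,
        stationary=stationary_points(params),
        residuals=resid,
        rss=rss,
        r2=_r2(rss, data.response),
        aicc=aicc(rss, n, 5),
        n_starts_tried=len(starts),
        converged=any_ok,
        dose_scale=xscale,
    )


# ---------------------------------------------------------------------------
# segmented (linear-plateau) regression
# ---------------------------------------------------------------------------


@dataclass
class SegmentedFit:
    """Continuous two-phase linear-plateau fit.

    ``orientation`` says which side of the breakpoint carries the sloped
    phase: ``ascending-plateau`` rises then flattens (the classic
    broken-line requirement model); ``plateau-ascending`` is flat then
    rises (e.g. plasma AA accumulating past the requirement).
    """

    breakpoint: float
    pre_slope: float
    intercept: float
    plateau: float
    orientation: str
    residuals: np.ndarray
    rss: float
    r2: float
    aicc: float
    degenerate: bool = False

    model_name: str = "linear-plateau"
    n_params: int = 3

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.orientation == ASCENDING_PLATEAU:
            h = np.minimum(x - self.breakpoint, 0.0)
        else:
            h = np.maximum(x - self.breakpoint, 0.0)
        out = self.plateau + self.pre_slope * h
        return out if out.ndim else float(out)


def _plateau_profile_rss(x, y, bps, orientation):
    """Closed-form OLS of (plateau, slope) for every breakpoint, vectorised."""
    diff = x[None, :] - bps[:, None]
    h = np.minimum(diff, 0.0) if orientation == ASCENDING_PLATEAU else np.maximum(diff, 0.0)
    n = x.size
    sh = h.sum(axis=1)
    shh = (h * h).sum(axis=1)
    sy = y.sum()
    shy = h @ y
    denom = n * shh - sh * sh
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, (n * shy - sh * sy) / np.where(denom > 0, denom, 1.0), 0.0)
    p = (sy - s * sh) / n
    resid = p[:, None] + s[:, None] * h - y[None, :]
    return (resid * resid).sum(axis=1), p, s


def fit_segmented(
    data: DoseResponseTable,
    orientation: str = "auto",
    *,
    collapse_replicates: bool = False,
    n_grid: int = 1001,
) -> SegmentedFit:
    """Fit a continuous linear-plateau model.

    The breakpoint is profiled over ``n_grid`` equally spaced candidates
    (plus the observed dose levels) with the two linear coefficients
    solved in closed form at each, then polished by bounded scalar
    minimisation around the best grid cell.  ``orientation='auto'``
    tries both phase orders and keeps the lower-RSS one.
    """
    if collapse_replicates:
        data = data.level_means()
    if len(data) < 4:
        raise ValueError(f"need at least 4 observations, got {len(data)}")
    if data.n_levels < 3:
        raise ValueError(f"need at least 3 distinct dose levels, got {data.n_levels}")
    x, y = data.dose, data.response
    n = len(data)

    if np.ptp(y) == 0.0:
        resid = np.zeros_like(y)
        return SegmentedFit(
            breakpoint=float(x.min()),
            pre_slope=0.0,
            intercept=float(y[0]),
            plateau=float(y[0]),
            orientation=ASCENDING_PLATEAU if orientation in ("auto", ASCENDING_PLATEAU) else orientation,
            residuals=resid,
            rss=0.0,
            r2=1.0,
            aicc=aicc(0.0, n, 3),
            degenerate=True,
        )

    orientations = (
        (ASCENDING_PLATEAU, PLATEAU_ASCENDING) if orientation == "auto" else (orientation,)
    )
    for o in orientations:
        if o not in (ASCENDING_PLATEAU, PLATEAU_ASCENDING):
            raise ValueError(f"unknown orientation {o!r}")

    lo, hi = float(x.min()), float(x.max())
    grid = np.union1d(np.linspace(lo, hi, n_grid), np.unique(x))

    best = None  # (rss, bp, plateau, slope, orientation)
    for o in orientations:
        rss_prof, p_prof, s_prof = _plateau_profile_rss(x, y, grid, o)
        i = int(np.argmin(rss_prof))
        cand = (float(rss_prof[i]), float(grid[i]), float(p_prof[i]), float(s_prof[i]), o)
        # polish within the bracketing grid cells
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, grid.size - 1)]
        if bhi > blo:
            def rss_at(bp, _o=o):
                r, _, _ = _plateau_profile_rss(x, y, np.array([bp]), _o)
                return float(r[0])

            opt = minimize_scalar(rss_at, bounds=(blo, bhi), method="bounded",
                                  options={"xatol": 1e-10 * (hi - lo)})
            if opt.fun < cand[0]:
                r2_, p2_, s2_ = _plateau_profile_rss(x, y, np.array([opt.x]), o)
                cand = (float(r2_[0]), float(opt.x), float(p2_[0]), float(s2_[0]), o)
        if best is None or cand[0] < best[0]:
            best = cand

    rss, bp, plateau, slope, o = best
    fit = SegmentedFit(
        breakpoint=bp,
        pre_slope=slope,
        intercept=plateau - slope * bp if o == ASCENDING_PLATEAU else plateau,
        plateau=plateau,
        orientation=o,
        residuals=np.empty(0),
        rss=rss,
        r2=_r2(rss, y),
        aicc=aicc(rss, n, 3),
    )
    fit.residuals = y - fit.predict(x)
    # recompute rss from the realised curve so the reported value is
    # exactly consistent with predict()
    fit.rss = float(fit.residuals @ fit.residuals)
    fit.r2 = _r2(fit.rss, y)
    fit.aicc = aicc(fit.rss, n, 3)
    return fit


# ---------------------------------------------------------------------------
# remaining candidate models
# ---------------------------------------------------------------------------


@dataclass
class QuadraticFit:
    coef: np.ndarray  # highest power first, np.polyval convention
    residuals: np.ndarray
    rss: float
    r2: float
    aicc: float
    model_name: str = "quadratic"
    n_params: int = 3

    def predict(self, x):
        return np.polyval(self.coef, np.asarray(x, dtype=float))


@dataclass
class QuadPlateauFit:
    """Quadratic rising to its vertex, then a flat plateau (smooth join)."""

    a: float
    b: float
    c: float  # c < 0; vertex at x0 = -b/(2c)
    breakpoint: float
    plateau: float
    residuals: np.ndarray
    rss: float
    r2: float
    aicc: float
    model_name: str = "quadratic-plateau"
    n_params: int = 3

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        xx = np.minimum(x, self.breakpoint)
        out = self.a + self.b * xx + self.c * xx * xx
        return out if out.ndim else float(out)


@dataclass
class LogisticFit:
    """Four-parameter logistic: baseline + amplitude * expit(f*(x - m))."""

    baseline: float
    amplitude: float
    midpoint: float
    rate: float
    residuals: np.ndarray
    rss: float
    r2: float
    aicc: float
    model_name: str = "logistic"
    n_params: int = 4

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = self.baseline + self.amplitude * expit(self.rate * (x - self.midpoint))
        return out if out.ndim else float(out)


def _fit_quadratic(data: DoseResponseTable) -> QuadraticFit:
    coef = np.polyfit(data.dose, data.response, 2)
    resid = data.response - np.polyval(coef, data.dose)
    rss = float(resid @ resid)
    return QuadraticFit(coef, resid, rss, _r2(rss, data.response),
                        aicc(rss, len(data), 3))


def _fit_quad_plateau(data: DoseResponseTable) -> QuadPlateauFit:
    x, y = data.dose, data.response
    xs, ys, (x0, xr), (y0, yr) = _scaled_xy(data)

    def resid_fn(theta):
        a, b, lnegc = theta
        c = -math.exp(lnegc)
        bp = min(max(-b / (2 * c), xs.min()), xs.max() + 1.0)
        xx = np.minimum(xs, bp)
        return a + b * xx + c * xx * xx - ys

    q = np.polyfit(xs, ys, 2)
    lnegc0 = math.log(max(-q[0], 1e-3))
    best = None
    for theta0 in ([q[2], q[1], lnegc0], [0.0, 2.0, math.log(1.0)], [0.0, 4.0, math.log(4.0)]):
        try:
            res = least_squares(resid_fn, theta0, method="trf",
                                ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=300)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    a_s, b_s, lnegc = best.x
    c_s = -math.exp(lnegc)
    bp_s = min(max(-b_s / (2 * c_s), xs.min()), xs.max() + 1.0)
    # back-transform the quadratic a_s + b_s*x' + c_s*x'^2, x' = (x-x0)/xr
    c_r = c_s * yr / xr**2
    b_r = b_s * yr / xr - 2 * c_r * x0
    a_r = y0 + yr * a_s - (b_s * yr / xr) * x0 + c_r * x0**2
    bp = x0 + bp_s * xr
    fit = QuadPlateauFit(
        a=a_r, b=b_r, c=c_r, breakpoint=bp,
        plateau=a_r + b_r * bp + c_r * bp * bp,
        residuals=np.empty(0), rss=0.0, r2=0.0, aicc=0.0,
    )
    fit.residuals = y - fit.predict(x)
    fit.rss = float(fit.residuals @ fit.residuals)
    fit.r2 = _r2(fit.rss, y)
    fit.aicc = aicc(fit.rss, len(data), 3)
    return fit


def _fit_logistic(data: DoseResponseTable) -> LogisticFit:
    x, y = data.dose, data.response
    xs, ys, (x0, xr), (y0, yr) = _scaled_xy(data)

    def resid_fn(theta):
        base, lamp, m, lf = theta
        return base + math.exp(lamp) * expit(math.exp(lf) * (xs - m)) - ys

    lo = np.array([-1e6, -30.0, -3.0, math.log(0.2)])
    hi = np.array([1e6, 16.0, 4.0, math.log(200.0)])
    best = None
    for m0 in (0.25, 0.5, 0.75):
        for f0 in (2.0, 5.0, 10.0):
            theta0 = np.array([float(ys.min()), 0.0, m0, math.log(f0)])
            try:
                res = least_squares(resid_fn, theta0, bounds=(lo, hi), method="trf",
                                    ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=300)
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    base_s, lamp, m_s, lf = best.x
    fit = LogisticFit(
        baseline=y0 + yr * base_s,
        amplitude=yr * math.exp(lamp),
        midpoint=x0 + m_s * xr,
        rate=math.exp(lf) / xr,
        residuals=np.empty(0), rss=0.0, r2=0.0, aicc=0.0,
    )
    fit.residuals = y - fit.predict(x)
    fit.rss = float(fit.residuals @ fit.residuals)
    fit.r2 = _r2(fit.rss, y)
    fit.aicc = aicc(fit.rss, len(data), 3)
    return fit


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class ModelSelection:
    """Ranked candidate fits for one response."""

    candidates: list[tuple[str, float, float]]  # (name, aicc, r2), ranked
    winner: str
    delta_aicc: Optional[float]  # winner to runner-up; None for one candidate
    fits: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)  # (name, reason)


_MIN_N = {
    "linear-logistic": 5,
    "logistic": 5,
    "linear-plateau": 4,
    "quadratic-plateau": 4,
    "quadratic": 4,
}


def _fit_one(name: str, data: DoseResponseTable, collapse: bool):
    if name == "linear-logistic":
        return fit_linlog(data, collapse_replicates=collapse)
    if name == "linear-plateau":
        return fit_segmented(data, collapse_replicates=collapse)
    d = data.level_means() if collapse else data
    if name == "quadratic-plateau":
        return _fit_quad_plateau(d)
    if name == "logistic":
        return _fit_logistic(d)
    if name == "quadratic":
        return _fit_quadratic(d)
    raise ValueError(f"unknown candidate model {name!r}")


def fit_candidates(
    data: DoseResponseTable,
    candidates: Sequence[str] = CANDIDATE_MODELS,
    *,
    collapse_replicates: bool = False,
) -> ModelSelection:
    """Fit every candidate model and rank by AICc.

    Ties (ΔAICc < 1e-6) are broken by fewer parameters, then by model
    name; candidates with too few observations are skipped and recorded
    rather than raised.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    fits: dict[str, object] = {}
    skipped: list[tuple[str, str]] = []
    n_eff = data.n_levels if collapse_replicates else len(data)
    for name in candidates:
        if name not in _N_PARAMS:
            raise ValueError(f"unknown candidate model {name!r}")
        if n_eff < _MIN_N[name]:
            skipped.append((name, f"needs >= {_MIN_N[name]} observations, have {n_eff}"))
            continue
        try:
            fits[name] = _fit_one(name, data, collapse_replicates)
        except (ValueError, RuntimeError) as exc:
            skipped.append((name, str(exc)))
    if not fits:
        raise ValueError(
            "no candidate could be fitted: "
            + "; ".join(f"{n}: {r}" for n, r in skipped)
        )
    def _rank_key(kv):
        name, fit = kv
        q = fit.aicc if math.isinf(fit.aicc) else round(fit.aicc / 1e-6) * 1e-6
        return (q, _N_PARAMS[name], name)

    ranked = sorted(fits.items(), key=_rank_key)
    table = [(name, fit.aicc, fit.r2) for name, fit in ranked]
    delta = table[1][1] - table[0][1] if len(table) > 1 else None
    return ModelSelection(
        candidates=table,
        winner=table[0][0],
        delta_aicc=delta,
        fits=fits,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# dose utilities
# ---------------------------------------------------------------------------


def normalize_dose(concentration, requirement):
    """Express a dietary concentration as a percentage of the requirement.

    Returns ``100 * concentration / requirement`` — the relative-dose
    axis used to pool titration studies with different absolute scales.
    """
    requirement = np.asarray(requirement, dtype=float)
    if np.any(requirement <= 0):
        raise ValueError("requirement must be > 0")
    out = 100.0 * np.asarray(concentration, dtype=float) / requirement
    return out if out.ndim else float(out)


def nearest_treatment(value: float, treatments: Iterable[float]) -> float:
    """Map an estimated dose onto the nearest actual treatment level.

    Exact midpoints between two levels resolve to the larger one.
    """
    grid = np.sort(np.asarray(list(treatments), dtype=float))
    if grid.size == 0:
        raise ValueError("empty treatment grid")
    dist = np.abs(grid - float(value))
    # argmin ties resolve to the larger dose: scan from the top
    idx = grid.size - 1 - int(np.argmin(dist[::-1]))
    return float(grid[idx])
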