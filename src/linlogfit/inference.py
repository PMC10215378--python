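"""Uncertainty quantification and the Rmin-vs-breakpoint comparison.

The headline scientific question this package supports: when a growth
response follows the rise-dip-rise linear-logistic curve and a companion
physiological response (milk yield, titre, plasma AA, ...) shows a
broken-line pattern, does the companion's breakpoint sit at the growth
curve's local-minimum dose Rmin rather than at its local-maximum dose
Rmax?  ``compare_rmin_to_breakpoint`` operationalises "coincides with"
as nearest-inflection by absolute dose distance, optionally mapped onto
the actual treatment grid.

Uncertainty comes from a case-resampling bootstrap stratified by dose
level: within each level, observations are resampled with replacement,
preserving the design's level structure.  Intervals are percentile
intervals.  Replicate fits that land in a regime without stationary
doses contribute nothing to the Rmax/Rmin intervals and are counted as
failed, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import DoseResponseTable
from .fitting import LinLogFit, SegmentedFit, fit_linlog, fit_segmented, nearest_treatment
from .model import TWO_POINTS

__all__ = [
    "BootstrapResult",
    "CoincidenceReport",
    "bootstrap_ci",
    "compare_rmin_to_breakpoint",
    "coverage_calibration",
]


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for the fitted inflection doses.

    ``point``, ``ci_low`` and ``ci_high`` are keyed by quantity name
    (``rmax``/``rmin`` for a linear-logistic fit, ``breakpoint`` for a
    segmented fit).  ``replicates`` holds the raw per-replicate
    estimates (NaN where a replicate failed for that quantity).
    """

    b_replicates: int
    alpha: float
    point: dict
    ci_low: dict
    ci_high: dict
    failed_replicates: int
    seed: int
    unreliable: bool
    replicates: dict = field(repr=False, default_factory=dict)


def _stratified_indices(dose: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.empty(dose.size, dtype=int)
    pos = 0
    for level in np.unique(dose):
        members = np.flatnonzero(dose == level)
        take = rng.integers(0, members.size, size=members.size)
        idx[pos : pos + members.size] = members[take]
        pos += members.size
    return idx


def bootstrap_ci(
    data: DoseResponseTable,
    fit_procedure: str = "linlog",
    *,
    B: int = 1000,
    alpha: float = 0.10,
    seed: int = 0,
    orientation: str = "auto",
) -> BootstrapResult:
    """Case bootstrap, stratified by dose level, for Rmax/Rmin or breakpoint.

    ``fit_procedure`` is ``'linlog'`` or ``'segmented'``.  Replicate
    streams are spawned deterministically from the root seed, so results
    are reproducible regardless of execution order.  Linear-logistic
    replicates are warm-started at the full-data estimate.  If more than
    half the replicates fail, the result is flagged ``unreliable``.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if fit_procedure not in ("linlog", "segmented"):
        raise ValueError(f"unknown fit procedure {fit_procedure!r}")

    if fit_procedure == "linlog":
        full = fit_linlog(data)
        if full.stationary.regime != TWO_POINTS:
            raise ValueError(
                f"full-data fit has regime {full.stationary.regime!r}: no "
                "stationary doses to bootstrap"
            )
        quantities = ("rmax", "rmin")
        point = {"rmax": full.stationary.rmax, "rmin": full.stationary.rmin}
    else:
        seg_full = fit_segmented(data, orientation=orientation)
        quantities = ("breakpoint",)
        point = {"breakpoint": seg_full.breakpoint}
        # hold orientation fixed across replicates for comparability
        orientation_fixed = seg_full.orientation

    reps = {q: np.full(B, np.nan) for q in quantities}
    failed = 0
    streams = np.random.SeedSequence(seed).spawn(B)
    for i in range(B):
        rng = np.random.default_rng(streams[i])
        sample = data.subset(_stratified_indices(data.dose, rng))
        try:
            if fit_procedure == "linlog":
                fit = fit_linlog(
                    sample, start_params=full.params, include_default_starts=False
                )
                if fit.stationary.regime == TWO_POINTS:
                    reps["rmax"][i] = fit.stationary.rmax
                    reps["rmin"][i] = fit.stationary.rmin
                else:
                    failed += 1
            else:
                seg = fit_segmented(sample, orientation=orientation_fixed, n_grid=201)
                if seg.degenerate:
                    failed += 1
                else:
                    reps["breakpoint"][i] = seg.breakpoint
        except (ValueError, RuntimeError):
            failed += 1

    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    ci_low, ci_high = {}, {}
    for q in quantities:
        ok = reps[q][np.isfinite(reps[q])]
        if ok.size:
            ci_low[q] = float(np.quantile(ok, lo_q))
            ci_high[q] = float(np.quantile(ok, hi_q))
        else:
            ci_low[q] = math.nan
            ci_high[q] = math.nan
    return BootstrapResult(
        b_replicates=B,
        alpha=alpha,
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        failed_replicates=failed,
        seed=seed,
        unreliable=failed > B / 2,
        replicates=reps,
    )


@dataclass
class CoincidenceReport:
    """Where a companion response's breakpoint sits relative to Rmax/Rmin."""

    rmax: Optional[float]
    rmin: Optional[float]
    breakpoint: Optional[float]
    distance_to_rmax: Optional[float]
    distance_to_rmin: Optional[float]
    nearest_inflection: Optional[str]  # "Rmin" | "Rmax" | None
    nearest_treatment_of_rmin: Optional[float]
    primary_regime: str
    message: str = ""
    primary_fit: Optional[LinLogFit] = field(repr=False, default=None)
    companion_fit: Optional[SegmentedFit] = field(repr=False, default=None)


def compare_rmin_to_breakpoint(
    primary: DoseResponseTable,
    companion: DoseResponseTable,
    treatments: Optional[list] = None,
    *,
    orientation: str = "auto",
) -> CoincidenceReport:
    """Fit both responses and locate the companion breakpoint.

    The primary (growth/retention) table gets the linear-logistic fit;
    the companion gets segmented regression.  If the primary fit has no
    interior dip (monotone regime) the rise-dip-rise pattern is not
    detectable in these data and the report says so instead of
    inventing distances.
    """
    if primary.dose_unit and companion.dose_unit and primary.dose_unit != companion.dose_unit:
        raise ValueError(
            f"dose units differ: primary {primary.dose_unit!r} vs "
            f"companion {companion.dose_unit!r}"
        )
    fit = fit_linlog(primary)
    if fit.stationary.regime != TWO_POINTS:
        return CoincidenceReport(
            rmax=None,
            rmin=None,
            breakpoint=None,
            distance_to_rmax=None,
            distance_to_rmin=None,
            nearest_inflection=None,
            nearest_treatment_of_rmin=None,
            primary_regime=fit.stationary.regime,
            message=(
                "primary response has no inflection points (regime "
                f"{fit.stationary.regime!r}); the rise-dip-rise pattern is "
                "not detectable in these data"
            ),
            primary_fit=fit,
        )
    seg = fit_segmented(companion, orientation=orientation)
    rmax, rmin = fit.stationary.rmax, fit.stationary.rmin
    d_rmax = abs(seg.breakpoint - rmax)
    d_rmin = abs(seg.breakpoint - rmin)
    return CoincidenceReport(
        rmax=rmax,
        rmin=rmin,
        breakpoint=seg.breakpoint,
        distance_to_rmax=d_rmax,
        distance_to_rmin=d_rmin,
        nearest_inflection="Rmin" if d_rmin <= d_rmax else "Rmax",
        nearest_treatment_of_rmin=(
            nearest_treatment(rmin, treatments) if treatments else None
        ),
        primary_regime=TWO_POINTS,
        primary_fit=fit,
        companion_fit=seg,
    )


def coverage_calibration(
    design,
    params=None,
    *,
    n_sims: int = 200,
    B: int = 200,
    alpha: float = 0.10,
    seed: int = 0,
    include_breakpoint: bool = False,
) -> dict:
    """Empirical bootstrap-interval coverage under known synthetic truth.

    Simulates ``n_sims`` studies from ``design``/``params`` with derived
    per-simulation seeds, builds a (1 - alpha) percentile interval for
    Rmax and Rmin in each (and for the companion breakpoint when
    ``include_breakpoint``), and reports the fraction of intervals that
    contain the generating truth.  Simulations whose full-data fit has
    no stationary doses yield no interval and are counted separately.
    """
    from dataclasses import replace

    from .synthetic import default_params, generate_primary, make_pair

    if params is None:
        params = default_params()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sims)
    hits = {"rmax": 0, "rmin": 0}
    totals = {"rmax": 0, "rmin": 0}
    if include_breakpoint:
        hits["breakpoint"] = 0
        totals["breakpoint"] = 0
    n_no_interval = 0
    for i in range(n_sims):
        states = children[i].generate_state(2)
        sim_seed = int(states[0] % (2**31))
        boot_seed = int(states[1] % (2**31))
        d = replace(design, seed=sim_seed)
        if include_breakpoint:
            pair = make_pair(d, params)
            table, truth = pair.primary, pair.truth
        else:
            table, truth = generate_primary(d, params)
        try:
            boot = bootstrap_ci(table, "linlog", B=B, alpha=alpha, seed=boot_seed)
        except ValueError:
            n_no_interval += 1
            continue
        for q in ("rmax", "rmin"):
            totals[q] += 1
            if boot.ci_low[q] <= truth[q] <= boot.ci_high[q]:
                hits[q] += 1
        if include_breakpoint:
            seg_boot = bootstrap_ci(
                pair.companion, "segmented", B=B, alpha=alpha, seed=boot_seed + 1
            )
            totals["breakpoint"] += 1
            if (
                seg_boot.ci_low["breakpoint"]
                <= truth["breakpoint"]
                <= seg_boot.ci_high["breakpoint"]
            ):
                hits["breakpoint"] += 1
    out = {
        "n_sims": n_sims,
        "B": B,
        "alpha": alpha,
        "n_without_interval": n_no_interval,
    }
    for q in totals:
        out[f"coverage_{q}"] = hits[q] / totals[q] if totals[q] else math.nan
        out[f"n_{q}"] = totals[q]
    return out
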