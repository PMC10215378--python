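"""Fitting: linear-logistic NLS, segmented regression, model selection."""

import numpy as np
import pytest

from linlogfit import (
    MONOTONE,
    TWO_POINTS,
    DoseResponseTable,
    LinLogParams,
    SyntheticDesign,
    fit_candidates,
    fit_linlog,
    fit_segmented,
    generate_primary,
    linlog_eval,
    nearest_treatment,
    normalize_dose,
    params_from_geometry,
)
from linlogfit.fitting import _plateau_profile_rss


class TestFitLinLog:
    def test_noiseless_recovery(self, ref_params, noiseless_table):
        fit = fit_linlog(noiseless_table)
        for name in ("a", "b", "c", "d", "f"):
            true = getattr(ref_params, name)
            est = getattr(fit.params, name)
            tol = 1e-4 * max(abs(true), 1.0)
            assert abs(est - true) <= tol, f"{name}: {est} vs {true}"
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.converged

    def test_pure_line_gives_monotone_regime(self):
        x = np.arange(1.0, 9.0)
        fit = fit_linlog(DoseResponseTable(x, 2.0 + 3.0 * x))
        assert fit.params.c * fit.params.f <= 4.0 * fit.params.b
        assert fit.stationary.regime == MONOTONE
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_noisy_rmin_recovery_within_5pct_of_range(self):
        params = params_from_geometry(97.0, 117.0, b=2.0, a=200.0)
        design = SyntheticDesign(seed=1)  # 6 levels over 77-127, 8 reps, 3% noise
        table, truth = generate_primary(design, params)
        fit = fit_linlog(table)
        assert fit.stationary.regime == TWO_POINTS
        assert abs(fit.stationary.rmin - truth["rmin"]) <= 0.05 * table.dose_range

    def test_rss_matches_recomputation(self, noiseless_table):
        design = SyntheticDesign(seed=5)
        table, _ = generate_primary(design)
        fit = fit_linlog(table)
        resid = table.response - linlog_eval(fit.params, table.dose)
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-12)

    def test_affine_dose_rescaling_invariance(self):
        table, _ = generate_primary(SyntheticDesign(seed=11))
        fit = fit_linlog(table)
        scaled = DoseResponseTable(table.dose * 10.0 + 5.0, table.response)
        fit2 = fit_linlog(scaled)
        grid = np.linspace(table.dose.min(), table.dose.max(), 50)
        np.testing.assert_allclose(
            fit.predict(grid), fit2.predict(grid * 10.0 + 5.0), rtol=1e-6
        )
        assert fit2.stationary.rmin == pytest.approx(
            10.0 * fit.stationary.rmin + 5.0, rel=1e-6
        )
        assert fit2.stationary.rmax == pytest.approx(
            10.0 * fit.stationary.rmax + 5.0, rel=1e-6
        )

    def test_collapse_replicates_fits_level_means(self):
        table, _ = generate_primary(SyntheticDesign(seed=3))
        fit = fit_linlog(table, collapse_replicates=True)
        means = table.level_means()
        resid = means.response - linlog_eval(fit.params, means.dose)
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-12)

    def test_too_few_points_raises(self, ref_params):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="at least 5"):
            fit_linlog(DoseResponseTable(x, linlog_eval(ref_params, x)))

    def test_constant_response_raises(self):
        x = np.arange(1.0, 9.0)
        with pytest.raises(ValueError, match="constant"):
            fit_linlog(DoseResponseTable(x, np.full_like(x, 7.0)))


class TestFitSegmented:
    def test_exact_two_segment_data(self):
        x = np.arange(1.0, 9.0)
        y = np.where(x <= 5.0, x, 5.0)
        seg = fit_segmented(DoseResponseTable(x, y))
        assert seg.breakpoint == pytest.approx(5.0, abs=1e-6)
        assert seg.pre_slope == pytest.approx(1.0, abs=1e-6)
        assert seg.plateau == pytest.approx(5.0, abs=1e-6)
        assert seg.orientation == "ascending-plateau"

    def test_plateau_then_rise_orientation_auto(self):
        x = np.arange(0.0, 10.0)
        y = np.where(x <= 4.0, 2.0, 2.0 + 0.5 * (x - 4.0))
        seg = fit_segmented(DoseResponseTable(x, y))
        assert seg.orientation == "plateau-ascending"
        assert seg.breakpoint == pytest.approx(4.0, abs=1e-6)
        assert seg.plateau == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 2, 9])
    def test_polish_beats_1000_point_grid(self, seed):
        rng = np.random.default_rng(seed)
        x = np.repeat(np.linspace(0, 10, 6), 4)
        y = np.minimum(x, 6.0) + rng.normal(0, 0.3, x.size)
        data = DoseResponseTable(x, y)
        seg = fit_segmented(data)
        grid = np.linspace(x.min(), x.max(), 1000)
        rss_grid, _, _ = _plateau_profile_rss(x, y, grid, seg.orientation)
        assert seg.rss <= rss_grid.min() + 1e-9

    def test_noisy_breakpoint_within_5pct_of_range(self):
        rng = np.random.default_rng(2)
        levels = np.linspace(77.0, 127.0, 6)
        x = np.repeat(levels, 8)
        mean = np.minimum(x, 100.0)  # breakpoint at 100
        y = mean + rng.normal(0, 0.01 * np.ptp(mean), x.size)
        seg = fit_segmented(DoseResponseTable(x, y))
        assert abs(seg.breakpoint - 100.0) <= 0.05 * (127.0 - 77.0)

    def test_breakpoint_stays_in_dose_range(self):
        rng = np.random.default_rng(17)
        x = np.repeat(np.linspace(0, 1, 5), 3)
        y = rng.normal(0, 1, x.size)
        seg = fit_segmented(DoseResponseTable(x, y))
        assert x.min() <= seg.breakpoint <= x.max()

    def test_constant_response_degenerate_flagged(self):
        x = np.arange(0.0, 6.0)
        seg = fit_segmented(DoseResponseTable(x, np.full_like(x, 3.0)))
        assert seg.degenerate
        assert seg.plateau == 3.0
        assert seg.pre_slope == 0.0


class TestFitCandidates:
    def test_noiseless_linlog_data_selects_linlog(self, noiseless_table):
        sel = fit_candidates(noiseless_table)
        assert sel.winner == "linear-logistic"
        assert sel.delta_aicc is not None and sel.delta_aicc > 0

    def test_noiseless_two_segment_data_selects_linear_plateau(self):
        x = np.arange(1.0, 9.0)
        y = np.where(x <= 5.0, x, 5.0)
        sel = fit_candidates(DoseResponseTable(x, y))
        assert sel.winner == "linear-plateau"

    def test_single_candidate(self, noiseless_table):
        sel = fit_candidates(noiseless_table, ["quadratic"])
        assert sel.winner == "quadratic"
        assert sel.delta_aicc is None

    def test_empty_candidate_set_raises(self, noiseless_table):
        with pytest.raises(ValueError, match="empty"):
            fit_candidates(noiseless_table, [])

    def test_insufficient_n_candidates_skipped(self, ref_params):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = linlog_eval(ref_params, x) + np.array([0.0, 0.01, -0.01, 0.0])
        sel = fit_candidates(DoseResponseTable(x, y))
        assert "linear-logistic" in {name for name, _ in sel.skipped}
        assert sel.winner in {"linear-plateau", "quadratic-plateau", "quadratic"}


class TestDoseUtilities:
    @pytest.mark.parametrize(
        "conc, req, expected", [(0.8, 1.0, 80.0), (1.0, 1.0, 100.0), (1.2, 0.8, 150.0)]
    )
    def test_normalize_dose(self, conc, req, expected):
        assert normalize_dose(conc, req) == pytest.approx(expected)

    def test_normalize_dose_rejects_nonpositive_requirement(self):
        with pytest.raises(ValueError, match="requirement"):
            normalize_dose(1.0, 0.0)

    @pytest.mark.parametrize(
        "value, grid, expected",
        [
            (116.2, [77, 87, 97, 107, 117, 127], 117.0),
            (112.0, [107, 117], 117.0),  # tie resolves to the larger dose
            (77.0, [77, 87], 77.0),
        ],
    )
    def test_nearest_treatment(self, value, grid, expected):
        assert nearest_treatment(value, grid) == expected

    def test_nearest_treatment_empty_grid(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_treatment(1.0, [])
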