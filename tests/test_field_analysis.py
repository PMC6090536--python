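"""Average time field, half-width measurement, and scalar-property diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timecellmap import (
    DegenerateFieldError,
    EmptyPopulationError,
    InvalidConfigError,
    LearningConfig,
    Population,
    ScalarRegime,
    TimeCell,
    TimeField,
    TimeGrid,
    average_time_field,
    firing_rate,
    lesion,
    make_fixture_population,
    make_uniform_population,
    measure_width,
    scalar_regime,
    scalar_report,
    timing_error,
    train,
    width_cell,
    width_learn,
)

HALF_MAX_FACTOR = math.sqrt(2 * math.log(2))


def single_cell_pop(peak=10.0, sigma=2.0, weight=1.0):
    return Population(
        cells=(TimeCell(peak, sigma, weight),), boundary=peak, cv=sigma / peak
    )


class TestAverageTimeField:
    def test_single_cell_field_is_its_gaussian(self):
        pop = single_cell_pop()
        grid = TimeGrid(0.0, 20.0, 0.01)
        field = average_time_field(pop, grid)
        np.testing.assert_allclose(
            field.values, firing_rate(pop.cells[0], grid.times), rtol=1e-14
        )

    def test_linearity_in_weights(self, fig2_t10):
        grid = TimeGrid(0.0, 20.0, 0.05)
        base = average_time_field(fig2_t10, grid)
        doubled = average_time_field(fig2_t10.with_weights([2.0] * 5), grid)
        np.testing.assert_allclose(doubled.values, 2 * base.values, rtol=1e-14)

    def test_empty_population_rejected(self, fig2_t10):
        empty = lesion(fig2_t10, "dorsal", 1.0)
        with pytest.raises(EmptyPopulationError):
            average_time_field(empty, TimeGrid(0.0, 20.0, 0.01))


class TestMeasureWidth:
    def test_single_cell_half_widths_match_analytic_formula(self):
        sigma = 2.0
        field = average_time_field(single_cell_pop(sigma=sigma), TimeGrid(0, 20, 0.001))
        report = measure_width(field)
        expected = sigma * HALF_MAX_FACTOR
        assert report.peak_time == pytest.approx(10.0, abs=1e-3)
        assert report.half_width_left == pytest.approx(expected, abs=1e-3)
        assert report.half_width_right == pytest.approx(expected, abs=1e-3)
        assert report.half_width_mean == pytest.approx(width_cell(sigma), abs=1e-3)

    def test_undefined_side_reported_as_nan(self):
        # grid stops right at the peak: the right side never reaches half max
        field = average_time_field(single_cell_pop(), TimeGrid(0.0, 10.0, 0.001))
        report = measure_width(field)
        assert math.isnan(report.half_width_right)
        assert report.half_width_mean == pytest.approx(report.half_width_left)

    def test_constant_field_rejected(self):
        grid = TimeGrid(0.0, 1.0, 0.01)
        field = TimeField(grid=grid, values=np.ones_like(grid.times))
        with pytest.raises(DegenerateFieldError):
            measure_width(field)

    def test_trial_two_field_narrower_than_trial_one(self, fig2_t10):
        grid = TimeGrid(0.0, 21.0, 0.01)
        widths = []
        pop = fig2_t10
        cfg = LearningConfig(criterion=10.0, epsilon=0.5, n_trials=1)
        for _ in range(2):
            pop, _ = train(pop, cfg)
            widths.append(measure_width(average_time_field(pop, grid)).half_width_mean)
        assert widths[1] < widths[0]


class TestAnalyticWidths:
    def test_width_cell_formula_and_linearity(self):
        assert width_cell(1.0) == pytest.approx(HALF_MAX_FACTOR)
        assert width_cell(2.0) == pytest.approx(2 * width_cell(1.0))
        with pytest.raises(InvalidConfigError):
            width_cell(0.0)

    def test_width_learn_is_epsilon_and_halves_weight(self):
        eps = 0.5
        assert width_learn(eps) == eps
        # weight profile 1/(d+eps): value at d=eps is half the value at d=0
        w0 = 1.0 / (0.0 + eps)
        w_at_eps = 1.0 / (eps + eps)
        assert w_at_eps == pytest.approx(w0 / 2)

    @pytest.mark.parametrize(
        "sigma,eps,expected",
        [
            (2.0, 0.5, ScalarRegime.SCALAR),
            (0.1, 0.5, ScalarRegime.LEARNING_LIMITED),
        ],
    )
    def test_regime_classification(self, sigma, eps, expected):
        assert scalar_regime(sigma, eps) == expected

    def test_regime_flips_exactly_at_boundary(self):
        """The scalar regime requires sigma*sqrt(2 ln 2) strictly above eps;
        the tie classifies as learning-limited."""
        eps = 0.7
        sigma_star = eps / HALF_MAX_FACTOR
        assert scalar_regime(sigma_star, eps) == ScalarRegime.LEARNING_LIMITED
        assert scalar_regime(sigma_star * (1 + 1e-9), eps) == ScalarRegime.SCALAR
        assert scalar_regime(sigma_star * (1 - 1e-9), eps) == ScalarRegime.LEARNING_LIMITED


class TestTimingError:
    def test_sparse_fixture_error_is_two_seconds(self, sparse_t10):
        assert timing_error(sparse_t10, 10.0) == 2.0

    def test_exact_coverage_gives_zero(self):
        pop = make_uniform_population(10.0, 30)  # includes a cell at exactly 10 s
        assert timing_error(pop, 10.0) == 0.0

    @given(n_cells=st.integers(2, 200), criterion=st.floats(1.0, 50.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_uniform_population_error_bounded_by_half_spacing(self, n_cells, criterion):
        pop = make_uniform_population(criterion, n_cells)
        spacing = pop.boundary / n_cells
        assert timing_error(pop, criterion) <= spacing / 2 + 1e-9 * criterion


class TestFieldPeakBehaviour:
    def test_uniform_population_peak_near_criterion(self):
        """With uniform coverage the trained field peaks within half an
        inter-cell spacing of T (plus a grid step)."""
        for n_cells in (10, 30, 100):
            pop = make_uniform_population(10.0, n_cells)
            trained, _ = train(pop, LearningConfig(criterion=10.0, n_trials=1))
            grid = TimeGrid.for_population(trained, criterion=10.0)
            report = measure_width(average_time_field(trained, grid))
            spacing = pop.boundary / n_cells
            assert abs(report.peak_time - 10.0) <= spacing / 2 + grid.step

    def test_sparse_population_peak_biased_toward_nearest_cell(self, sparse_t10):
        """Sparse asymmetric coverage pulls the field peak to ~8 s, the
        nearest available cell, not the 10 s criterion."""
        trained, _ = train(sparse_t10, LearningConfig(criterion=10.0, n_trials=1))
        report = measure_width(average_time_field(trained, TimeGrid(0, 35, 0.01)))
        assert abs(report.peak_time - 8.0) < abs(report.peak_time - 10.0)

    def test_peak_location_invariant_to_population_size(self):
        """Populations of 10, 100 and 1000 cells place the field peak within
        one coarse inter-cell spacing of each other."""
        peaks = []
        for n_cells in (10, 100, 1000):
            pop = make_uniform_population(10.0, n_cells)
            trained, _ = train(pop, LearningConfig(criterion=10.0, n_trials=1))
            grid = TimeGrid.for_population(trained, criterion=10.0)
            peaks.append(measure_width(average_time_field(trained, grid)).peak_time)
        coarse_spacing = 30.0 / 10
        assert max(peaks) - min(peaks) <= coarse_spacing

    def test_lesion_shifts_peak_directionally(self):
        """Removing dorsal (long-duration) cells shifts the field peak to
        shorter times; removing ventral cells shifts it longer."""
        pop = make_uniform_population(10.0, 30)
        trained, _ = train(pop, LearningConfig(criterion=10.0, n_trials=1))
        grid = TimeGrid.for_population(trained, criterion=10.0)
        pre = measure_width(average_time_field(trained, grid)).peak_time
        dorsal = lesion(trained, "dorsal", 0.7)
        ventral = lesion(trained, "ventral", 0.35)
        peak_d = measure_width(average_time_field(dorsal, grid)).peak_time
        peak_v = measure_width(average_time_field(ventral, grid)).peak_time
        assert peak_d < pre
        assert peak_v > pre


class TestScaleCovariance:
    @given(k=st.floats(0.2, 20.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_full_pipeline_scales_exactly(self, k):
        """Scaling T, every peak time, sigma, epsilon and the grid by k
        scales the field peak and half-widths by exactly k — the mechanism
        behind the scalar property."""
        T, eps, n_cells = 10.0, 0.5, 40
        base_pop = make_uniform_population(T, n_cells)
        scaled_pop = make_uniform_population(k * T, n_cells)
        base, _ = train(base_pop, LearningConfig(criterion=T, epsilon=eps, n_trials=2))
        scaled, _ = train(
            scaled_pop, LearningConfig(criterion=k * T, epsilon=k * eps, n_trials=2)
        )
        g = TimeGrid(0.0, 3 * T, 3 * T / 2000)
        gk = TimeGrid(0.0, k * 3 * T, k * 3 * T / 2000)
        r = measure_width(average_time_field(base, g))
        rk = measure_width(average_time_field(scaled, gk))
        assert rk.peak_time == pytest.approx(k * r.peak_time, rel=1e-6)
        assert rk.half_width_mean == pytest.approx(k * r.half_width_mean, rel=1e-6)


class TestScalarReport:
    def test_identical_criteria_give_unit_ratio(self):
        df = scalar_report([10.0, 10.0], n_cells=50)
        assert df["width_ratio"].iloc[1] == pytest.approx(1.0)

    def test_width_ratio_tracks_criterion_ratio_when_epsilon_scales(self):
        df = scalar_report([10.0, 30.0], n_cells=50, scale_epsilon=True)
        assert df["width_ratio"].iloc[1] == pytest.approx(3.0, rel=1e-3)

    def test_monotone_widths_across_criteria(self):
        df = scalar_report([10.0, 20.0, 40.0], n_cells=50)
        assert df["half_width_mean"].is_monotonic_increasing

    def test_single_criterion_rejected(self):
        with pytest.raises(InvalidConfigError):
            scalar_report([10.0])
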