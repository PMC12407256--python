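import numpy as np
import pytest
from scipy import stats

from msquant.simulate import (
    LABEL_THRESHOLD_FRACTION,
    AcquisitionMode,
    CalibrationDesign,
    InvalidGridError,
    LabeledDataset,
    NoiseModel,
    PeakShapeParams,
    ShapeDistribution,
    generate_calibration_run,
    generate_dataset,
    simulate_peak_shape,
    simulate_window_pair,
    truth_labels,
)
from msquant.windows import WINDOW_LENGTH, window_grid


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(sigma=0.0), dict(sigma=-1.0), dict(tail_tau=-0.1),
         dict(split_depth=1.0), dict(split_depth=-0.1)],
    )
    def test_bad_shape_params(self, kwargs):
        with pytest.raises(ValueError):
            PeakShapeParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(additive_sd=-1.0), dict(amplitude_cv=-0.1), dict(baseline_level=-5.0)],
    )
    def test_bad_noise_params(self, kwargs):
        with pytest.raises(ValueError):
            NoiseModel(**kwargs)

    def test_levels_must_increase(self):
        with pytest.raises(ValueError):
            CalibrationDesign(levels=(10.0, 10.0, 20.0))

    def test_levels_must_be_positive(self):
        with pytest.raises(ValueError):
            CalibrationDesign(levels=(0.0, 10.0, 20.0))

    def test_replicates_at_least_one(self):
        with pytest.raises(ValueError):
            CalibrationDesign(replicates=0)


class TestSimulatePeakShape:
    grid = np.arange(-2.0, 2.0, 0.01)

    def test_zero_area_gives_zero_vector(self, gaussian_shape):
        y = simulate_peak_shape(0.0, 0.0, gaussian_shape, self.grid)
        assert not y.any()

    def test_gaussian_area_matches_quadrature(self):
        shape = PeakShapeParams(sigma=0.05)
        y = simulate_peak_shape(0.0, 1.0, shape, self.grid)
        rect = y.sum() * 0.01
        # oracle: analytic Gaussian mass over the window
        exact = stats.norm.cdf(2.0, scale=0.05) - stats.norm.cdf(-2.0, scale=0.05)
        assert rect == pytest.approx(exact, abs=1e-3)
        assert rect == pytest.approx(1.0, abs=1e-3)

    def test_tailed_peak_shifts_first_moment(self):
        tailed = simulate_peak_shape(
            0.0, 1.0, PeakShapeParams(sigma=0.05, tail_tau=0.1), self.grid
        )
        pure = simulate_peak_shape(0.0, 1.0, PeakShapeParams(sigma=0.05), self.grid)
        m1_tailed = np.sum(self.grid * tailed) / tailed.sum()
        m1_pure = np.sum(self.grid * pure) / pure.sum()
        assert m1_tailed > m1_pure

    def test_notch_carves_apex(self):
        shape = PeakShapeParams(sigma=0.06, split_depth=0.5, split_offset=0.0)
        split = simulate_peak_shape(0.0, 1.0, shape, self.grid)
        pure = simulate_peak_shape(0.0, 1.0, PeakShapeParams(sigma=0.06), self.grid)
        center_idx = np.argmin(np.abs(self.grid))
        assert split[center_idx] == pytest.approx(0.5 * pure[center_idx])
        assert np.all(split <= pure + 1e-12)

    def test_nonnegative_output(self, rng):
        for _ in range(20):
            shape = ShapeDistribution().draw(rng)
            y = simulate_peak_shape(0.0, rng.uniform(0.1, 100.0), shape, self.grid)
            assert np.all(y >= 0)

    def test_area_conservation_without_split(self, rng):
        # property: rectangle-rule area within 0.5% of request when split_depth=0
        for _ in range(20):
            shape = PeakShapeParams(
                sigma=rng.uniform(0.03, 0.1), tail_tau=rng.choice([0.0, 0.05, 0.15])
            )
            area = rng.uniform(0.5, 1e5)
            y = simulate_peak_shape(0.0, area, shape, self.grid)
            assert y.sum() * 0.01 == pytest.approx(area, rel=5e-3)

    def test_negative_area_rejected(self, gaussian_shape):
        with pytest.raises(ValueError, match="area"):
            simulate_peak_shape(0.0, -1.0, gaussian_shape, self.grid)

    @pytest.mark.parametrize(
        "grid",
        [np.array([]), np.array([1.0]), np.array([0.0, 0.01, 0.05]),
         np.array([0.0, -0.01, -0.02])],
    )
    def test_invalid_grid_rejected(self, grid, gaussian_shape):
        with pytest.raises(InvalidGridError):
            simulate_peak_shape(0.0, 1.0, gaussian_shape, grid)


class TestTruthLabels:
    def test_threshold_rule(self):
        grid = window_grid(100.0)
        y = simulate_peak_shape(100.0, 50.0, PeakShapeParams(sigma=0.06), grid)
        mask = truth_labels(y).mask
        # brute force: contiguous run of points >= 1% of apex around the apex
        expected = (y >= LABEL_THRESHOLD_FRACTION * y.max()).astype(int)
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() > 0

    def test_zero_signal_all_zero(self):
        assert truth_labels(np.zeros(WINDOW_LENGTH)).mask.sum() == 0

    def test_single_contiguous_run(self, rng):
        from msquant.windows import longest_run

        grid = window_grid(100.0)
        for _ in range(20):
            shape = ShapeDistribution().draw(rng)
            y = simulate_peak_shape(100.0, 100.0, shape, grid)
            mask = truth_labels(y).mask
            np.testing.assert_array_equal(mask, longest_run(mask))


class TestSimulateWindowPair:
    def test_zero_conc_baseline_only(self, design, gaussian_shape):
        noise = NoiseModel(baseline_level=5.0, drift_slope=0.0,
                           additive_sd=0.0, amplitude_cv=0.0)
        pair, truth = simulate_window_pair(
            0.0, design, gaussian_shape, noise, AcquisitionMode.PARALLEL, seed=7
        )
        assert truth.analyte_area == 0.0
        np.testing.assert_allclose(pair.analyte.intensities, 5.0)
        assert truth.label_analyte.mask.sum() == 0

    def test_noiseless_ratio_identity(self, design, gaussian_shape, silent_noise):
        pair, truth = simulate_window_pair(
            160.0, design, gaussian_shape, silent_noise,
            AcquisitionMode.PARALLEL, seed=7,
        )
        expected = (design.response_factor_analyte * 160.0) / (
            design.response_factor_is * design.is_concentration
        )
        assert truth.true_ratio == pytest.approx(expected, abs=0.0)

    def test_seed_required(self, design, gaussian_shape, silent_noise):
        for bad in (None, 1.5, "1"):
            with pytest.raises(ValueError, match="seed"):
                simulate_window_pair(
                    10.0, design, gaussian_shape, silent_noise,
                    AcquisitionMode.PARALLEL, seed=bad,
                )

    def test_negative_conc_rejected(self, design, gaussian_shape, silent_noise):
        with pytest.raises(ValueError, match="concentration"):
            simulate_window_pair(
                -1.0, design, gaussian_shape, silent_noise,
                AcquisitionMode.PARALLEL, seed=1,
            )

    def test_parallel_shares_amplitude(self, design, gaussian_shape):
        noise = NoiseModel(baseline_level=0, drift_slope=0, additive_sd=0,
                           amplitude_cv=0.2)
        _, truth = simulate_window_pair(
            100.0, design, gaussian_shape, noise, AcquisitionMode.PARALLEL, seed=3
        )
        # shared amplitude cancels exactly in the ratio
        assert truth.true_ratio == pytest.approx(
            100.0 * design.response_factor_analyte
            / (design.response_factor_is * design.is_concentration), rel=1e-12,
        )

    def test_mode_contrast_rsd(self, design, gaussian_shape):
        # Monte-Carlo: parallel-mode ratio RSD < separate-mode ratio RSD
        noise = NoiseModel(baseline_level=0, drift_slope=0, additive_sd=0,
                           amplitude_cv=0.1)
        ratios = {}
        for mode in AcquisitionMode:
            vals = [
                simulate_window_pair(
                    100.0, design, gaussian_shape, noise, mode, seed=1000 + k
                )[1].true_ratio
                for k in range(30)
            ]
            vals = np.array(vals)
            ratios[mode] = vals.std(ddof=1) / vals.mean()
        assert ratios[AcquisitionMode.PARALLEL] < ratios[AcquisitionMode.SEPARATE]


class TestGenerateDataset:
    def test_empty(self, design, shape_dist, silent_noise):
        ds = generate_dataset(0, design, shape_dist, silent_noise, seed=1)
        assert ds.n_samples == 0 and ds.n_windows == 0 and ds.n_points == 0

    def test_dataset_bookkeeping(self, design, shape_dist, silent_noise):
        ds = generate_dataset(490, design, shape_dist, silent_noise, seed=1)
        assert ds.n_windows == 980
        assert ds.n_points == 392_000

    def test_reproducibility(self, design, shape_dist):
        noise = NoiseModel()
        a = generate_dataset(10, design, shape_dist, noise, seed=42)
        b = generate_dataset(10, design, shape_dist, noise, seed=42)
        np.testing.assert_array_equal(a.windows, b.windows)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)

    def test_different_seeds_differ(self, design, shape_dist):
        noise = NoiseModel()
        a = generate_dataset(5, design, shape_dist, noise, seed=1)
        b = generate_dataset(5, design, shape_dist, noise, seed=2)
        assert not np.array_equal(a.windows, b.windows)

    def test_negative_n_rejected(self, design, shape_dist, silent_noise):
        with pytest.raises(ValueError):
            generate_dataset(-1, design, shape_dist, silent_noise, seed=1)


class TestGenerateCalibrationRun:
    def test_eight_levels_one_replicate(self, design, gaussian_shape, silent_noise):
        run = generate_calibration_run(
            design, gaussian_shape, silent_noise, AcquisitionMode.PARALLEL, seed=1
        )
        assert len(run) == 8
        assert [r[0] for r in run] == list(design.levels)

    def test_replicates_multiply_pairs(self, gaussian_shape, silent_noise):
        design = CalibrationDesign(replicates=3)
        run = generate_calibration_run(
            design, gaussian_shape, silent_noise, AcquisitionMode.PARALLEL, seed=1
        )
        assert len(run) == 24

    def test_default_series_is_doubling_10_to_1280(self):
        design = CalibrationDesign.doubling(10.0, 1280.0)
        assert design.levels == tuple(10.0 * 2.0 ** k for k in range(8))
        assert design.levels[0] == 10.0 and design.levels[-1] == 1280.0

    def test_risperidone_series(self):
        design = CalibrationDesign.doubling(2.5, 320.0)
        assert design.levels[0] == 2.5 and design.levels[-1] == 320.0

    def test_mismatched_endpoints_rejected(self):
        with pytest.raises(ValueError, match="doubling"):
            CalibrationDesign.doubling(10.0, 1000.0)

    def test_determinism(self, design, gaussian_shape):
        noise = NoiseModel()
        a = generate_calibration_run(design, gaussian_shape, noise,
                                     AcquisitionMode.SEPARATE, seed=9)
        b = generate_calibration_run(design, gaussian_shape, noise,
                                     AcquisitionMode.SEPARATE, seed=9)
        for (_, pa, ta), (_, pb, tb) in zip(a, b):
            np.testing.assert_array_equal(pa.analyte.intensities,
                                          pb.analyte.intensities)
            assert ta.true_ratio == tb.true_ratio
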