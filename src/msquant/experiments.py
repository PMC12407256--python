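"""Canned desk-scale experiments used by the acceptance checks.

Each experiment recomputes its quantity from scratch through the public API:
generate the synthetic inputs, run the method, measure the result.  All
randomness is derived from the seed argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import SegmentationMetrics, evaluate_segmentation
from .quantify import CalibrationCurve, area_ratio, fit_calibration, peak_area
from .simulate import (
    AcquisitionMode,
    CalibrationDesign,
    NoiseModel,
    ShapeDistribution,
    generate_calibration_run,
    generate_dataset,
)
from .unet import UNetConfig, build_unet, predict_masks, train_model


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1, dtype=np.uint32)[0])
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


@dataclass(frozen=True)
class SegmentationExperiment:
    metrics: SegmentationMetrics
    loss_trace: list[float]
    n_train: int
    n_test: int


def segmentation_experiment(
    seed: int = 1,
    n_train: int = 1000,
    n_test: int = 250,
    unet_cfg: UNetConfig | None = None,
) -> SegmentationExperiment:
    """Train the default U-net on simulated window pairs and score it on a
    held-out test set (pointwise accuracy + mean |area ratio - 1|)."""
    design = CalibrationDesign()
    shape_dist = ShapeDistribution()
    noise = NoiseModel()
    s_train, s_test = _spawn_seeds(seed, 2)
    train = generate_dataset(n_train, design, shape_dist, noise, seed=s_train)
    test = generate_dataset(n_test, design, shape_dist, noise, seed=s_test)
    cfg = unet_cfg or UNetConfig(seed=seed)
    model = build_unet(cfg)
    result = train_model(model, train.flat_windows(), train.flat_labels(), cfg)
    preds = predict_masks(model, test.flat_windows())
    metrics = evaluate_segmentation(preds, test.flat_labels(), test.flat_windows())
    return SegmentationExperiment(
        metrics=metrics, loss_trace=result.loss_trace,
        n_train=train.n_windows, n_test=test.n_windows,
    )


#: Per-window amplitude CV that yields ~5% CV on the analyte/IS ratio when the
#: two windows draw independent amplitude factors (separate injections).
RATIO_CV_5PCT_PER_WINDOW = 0.05 / np.sqrt(2.0)


def calibration_experiment(
    seeds=range(1, 21),
    low: float = 10.0,
    high: float = 1280.0,
    amplitude_cv: float = RATIO_CV_5PCT_PER_WINDOW,
) -> tuple[list[CalibrationCurve], float]:
    """Repeated 8-level doubling-series calibrations with ~5% proportional
    ratio noise; ratios are measured by truth-mask peak areas and fitted by
    ordinary least squares.

    Returns the fitted curves and the true slope.
    """
    design = CalibrationDesign.doubling(low, high)
    noise = NoiseModel(amplitude_cv=amplitude_cv)
    shape_dist = ShapeDistribution()
    true_slope = design.response_factor_analyte / (
        design.response_factor_is * design.is_concentration
    )
    curves = []
    for seed in seeds:
        shape = shape_dist.draw(np.random.default_rng(int(seed) + 10_000))
        run = generate_calibration_run(
            design, shape, noise, AcquisitionMode.SEPARATE, seed=int(seed)
        )
        concs, ratios = [], []
        for conc, pair, truth in run:
            a = peak_area(pair.analyte.intensities, truth.label_analyte.mask)
            i = peak_area(pair.internal_standard.intensities, truth.label_is.mask)
            concs.append(conc)
            ratios.append(area_ratio(a, i))
        curves.append(fit_calibration(concs, ratios))
    return curves, true_slope


def mode_contrast_experiment(
    seed: int = 1, n_pairs: int = 30, amplitude_cv: float = 0.10,
    conc: float = 160.0,
) -> tuple[float, float]:
    """Ratio RSD (percent) over repeated acquisitions at one concentration,
    measured from truth-mask areas, under parallel vs. separate acquisition."""
    from .simulate import simulate_window_pair

    design = CalibrationDesign()
    noise = NoiseModel(amplitude_cv=amplitude_cv)
    shape_dist = ShapeDistribution()
    out = []
    for mode in (AcquisitionMode.PARALLEL, AcquisitionMode.SEPARATE):
        rng = np.random.default_rng(seed)
        ratios = []
        for _ in range(n_pairs):
            shape = shape_dist.draw(rng)
            pair, truth = simulate_window_pair(
                conc, design, shape, noise, mode, seed=int(rng.integers(0, 2**63 - 1))
            )
            a = peak_area(pair.analyte.intensities, truth.label_analyte.mask)
            i = peak_area(pair.internal_standard.intensities, truth.label_is.mask)
            ratios.append(area_ratio(a, i))
        ratios = np.array(ratios)
        out.append(100.0 * ratios.std(ddof=1) / ratios.mean())
    return out[0], out[1]
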