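"""Synthetic ion-trap MS2 fragment-window generator.

Produces labeled analyte / internal-standard window pairs with the peak
pathologies seen on miniature ion-trap instruments: Gaussian cores,
exponential tailing, apex splitting, baseline drift, additive noise, and a
per-acquisition global amplitude factor that is shared between the two
windows of a pair under parallel acquisition but drawn independently under
separate acquisition.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .windows import (
    GRID_SPACING,
    WINDOW_LENGTH,
    LabelVector,
    PeakWindow,
    longest_run,
    window_grid,
)

#: Width of the splitting notch as a fraction of the Gaussian core sigma.
NOTCH_WIDTH_FRACTION = 0.3

#: Fraction of the noiseless apex above which grid points are labeled as
#: belonging to the peak region.
LABEL_THRESHOLD_FRACTION = 0.01


class InvalidGridError(ValueError):
    """The m/z grid handed to the peak simulator is unusable."""


@dataclass(frozen=True)
class PeakShapeParams:
    """Shape of a single fragment-ion peak.

    sigma       -- m/z width of the Gaussian core (> 0)
    tail_tau    -- exponential tailing constant in m/z (0 = pure Gaussian)
    split_depth -- fraction in [0, 1) carved out of the apex by the notch
    split_offset-- m/z position of the notch center relative to the peak center
    """

    sigma: float = 0.06
    tail_tau: float = 0.0
    split_depth: float = 0.0
    split_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tail_tau < 0:
            raise ValueError(f"tail_tau must be >= 0, got {self.tail_tau}")
        if not 0 <= self.split_depth < 1:
            raise ValueError(f"split_depth must be in [0, 1), got {self.split_depth}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive disturbances applied after the truth areas are fixed.

    baseline_level -- constant intensity offset (>= 0)
    drift_slope    -- linear baseline drift, intensity per m/z
    additive_sd    -- SD of i.i.d. Gaussian noise per grid point (>= 0)
    amplitude_cv   -- CV of the per-acquisition log-normal amplitude factor
    """

    baseline_level: float = 20.0
    drift_slope: float = 5.0
    additive_sd: float = 10.0
    amplitude_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_level < 0:
            raise ValueError("baseline_level must be >= 0")
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(baseline_level=0.0, drift_slope=0.0, additive_sd=0.0, amplitude_cv=0.0)


class AcquisitionMode(str, enum.Enum):
    """Whether a window pair shares one amplitude draw (parallel MS2 after a
    single ion injection) or draws independently (separate injections)."""

    PARALLEL = "parallel"
    SEPARATE = "separate"


@dataclass(frozen=True)
class SimTruth:
    """Ground truth attached to a simulated window pair."""

    analyte_area: float
    is_area: float
    true_ratio: float
    label_analyte: LabelVector
    label_is: LabelVector


@dataclass(frozen=True)
class WindowPair:
    """Analyte window + internal-standard window from one acquisition."""

    analyte: PeakWindow
    internal_standard: PeakWindow


@dataclass(frozen=True)
class CalibrationDesign:
    """Layout of a calibration run.

    levels -- spiked concentrations (ng/mL), strictly increasing
    replicates -- acquisitions per level
    is_concentration -- internal-standard concentration (ng/mL)
    response_factor_analyte / response_factor_is -- area units per ng/mL
    analyte_mz / is_mz -- fragment m/z window centers (placeholder values;
        window position does not affect any statistic)
    """

    levels: tuple = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1280.0)
    replicates: int = 1
    is_concentration: float = 100.0
    response_factor_analyte: float = 100.0
    response_factor_is: float = 100.0
    analyte_mz: float = 260.2
    is_mz: float = 266.2

    def __post_init__(self) -> None:
        levels = tuple(float(c) for c in self.levels)
        if len(levels) == 0 or any(c <= 0 for c in levels):
            raise ValueError("levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.is_concentration <= 0:
            raise ValueError("is_concentration must be > 0")
        object.__setattr__(self, "levels", levels)

    @classmethod
    def doubling(cls, low: float, high: float, n_levels: int = 8, **kw) -> "CalibrationDesign":
        """Doubling series from ``low``; the default 8 levels from 10 reach 1280."""
        levels = tuple(low * 2.0 ** k for k in range(n_levels))
        if abs(levels[-1] - high) / high > 1e-9:
            raise ValueError(
                f"doubling series from {low} ends at {levels[-1]}, not {high}"
            )
        return cls(levels=levels, **kw)


@dataclass(frozen=True)
class ShapeDistribution:
    """Per-sample distribution over peak-shape parameters.

    With probability ``tail_prob`` a tailing constant is drawn uniformly from
    ``tail_tau_range``; with probability ``split_prob`` a notch is carved with
    depth from ``split_depth_range`` and offset from ``split_offset_range``.
    """

    sigma_range: tuple = (0.04, 0.09)
    tail_prob: float = 0.35
    tail_tau_range: tuple = (0.03, 0.15)
    split_prob: float = 0.25
    split_depth_range: tuple = (0.2, 0.6)
    split_offset_range: tuple = (-0.05, 0.05)

    def draw(self, rng: np.random.Generator) -> PeakShapeParams:
        sigma = rng.uniform(*self.sigma_range)
        tail = rng.uniform(*self.tail_tau_range) if rng.random() < self.tail_prob else 0.0
        if rng.random() < self.split_prob:
            depth = rng.uniform(*self.split_depth_range)
            offset = rng.uniform(*self.split_offset_range)
        else:
            depth, offset = 0.0, 0.0
        return PeakShapeParams(
            sigma=sigma, tail_tau=tail, split_depth=depth, split_offset=offset
        )


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidGridError("grid must be a 1-D array with >= 2 points")
    d = np.diff(grid)
    if not np.all(d > 0):
        raise InvalidGridError("grid must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
        raise InvalidGridError("grid must be uniformly spaced")
    return grid


def simulate_peak_shape(
    center: float, area: float, shape: PeakShapeParams, grid: np.ndarray
) -> np.ndarray:
    """Noiseless peak profile on ``grid`` with requested integrated ``area``.

    The core is a unit-area Gaussian (or exponentially modified Gaussian when
    ``tail_tau > 0``) scaled by ``area``; splitting multiplies intensities
    near ``center + split_offset`` by ``1 - split_depth * notch`` where the
    notch is a narrow Gaussian bump of width ``NOTCH_WIDTH_FRACTION * sigma``.
    The rectangle-rule integral approximates ``area`` before notching.
    """
    grid = _validate_grid(grid)
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    if area == 0:
        return np.zeros_like(grid)
    if shape.tail_tau > 1e-9 * shape.sigma:
        # exponnorm is the Gaussian convolved with Exp(1/tau); K = tau/sigma
        pdf = stats.exponnorm.pdf(
            grid, K=shape.tail_tau / shape.sigma, loc=center, scale=shape.sigma
        )
    else:
        pdf = stats.norm.pdf(grid, loc=center, scale=shape.sigma)
    y = area * pdf
    if shape.split_depth > 0:
        notch_sigma = NOTCH_WIDTH_FRACTION * shape.sigma
        notch = np.exp(
            -0.5 * ((grid - (center + shape.split_offset)) / notch_sigma) ** 2
        )
        y = y * (1.0 - shape.split_depth * notch)
    return y


def truth_labels(noiseless: np.ndarray) -> LabelVector:
    """Label the contiguous region where the noiseless peak exceeds
    ``LABEL_THRESHOLD_FRACTION`` of its apex (run containing the apex)."""
    noiseless = np.asarray(noiseless, dtype=float)
    apex = noiseless.max(initial=0.0)
    if apex <= 0:
        return LabelVector(mask=np.zeros(noiseless.size, dtype=np.int8))
    above = (noiseless >= LABEL_THRESHOLD_FRACTION * apex).astype(np.int8)
    # keep the run containing the apex (the threshold set is an interval for
    # unimodal shapes; notching can fray the boundary)
    apex_idx = int(np.argmax(noiseless))
    padded = np.concatenate(([0], above, [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    out = np.zeros_like(above)
    for s, e in zip(starts, ends):
        if s <= apex_idx < e:
            out[s:e] = 1
            break
    else:  # apex excluded only by pathological input; fall back to longest run
        out = longest_run(above)
    return LabelVector(mask=out)


def _amplitude_factor(rng: np.random.Generator, cv: float) -> float:
    """Log-normal factor with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    s2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2)))


def _require_seed(seed) -> int:
    if seed is None or isinstance(seed, bool) or not isinstance(seed, (int, np.integer)):
        raise ValueError("an integer seed is required for reproducibility")
    return int(seed)


def _render_window(
    center: float,
    area: float,
    shape: PeakShapeParams,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[PeakWindow, LabelVector]:
    grid = window_grid(center)
    clean = simulate_peak_shape(center, area, shape, grid)
    labels = truth_labels(clean)
    signal = clean + noise.baseline_level + noise.drift_slope * (grid - grid[0])
    if noise.additive_sd > 0:
        signal = signal + rng.normal(0.0, noise.additive_sd, size=grid.size)
    return PeakWindow(center_mz=center, intensities=signal), labels


def simulate_window_pair(
    analyte_conc: float,
    design: CalibrationDesign,
    shape: PeakShapeParams,
    noise: NoiseModel,
    mode: AcquisitionMode,
    seed: int,
) -> tuple[WindowPair, SimTruth]:
    """Simulate one acquisition: analyte + internal-standard windows.

    Truth areas are ``response_factor * concentration * amplitude`` with the
    amplitude drawn once per acquisition in parallel mode and once per window
    in separate mode; baseline, drift, and point noise are added afterwards.
    """
    seed = _require_seed(seed)
    if analyte_conc < 0:
        raise ValueError(f"analyte concentration must be >= 0, got {analyte_conc}")
    rng = np.random.default_rng(seed)
    mode = AcquisitionMode(mode)
    amp_a = _amplitude_factor(rng, noise.amplitude_cv)
    amp_i = amp_a if mode is AcquisitionMode.PARALLEL else _amplitude_factor(
        rng, noise.amplitude_cv
    )
    analyte_area = design.response_factor_analyte * analyte_conc * amp_a
    is_area = design.response_factor_is * design.is_concentration * amp_i
    win_a, lab_a = _render_window(design.analyte_mz, analyte_area, shape, noise, rng)
    win_i, lab_i = _render_window(design.is_mz, is_area, shape, noise, rng)
    truth = SimTruth(
        analyte_area=analyte_area,
        is_area=is_area,
        true_ratio=analyte_area / is_area,
        label_analyte=lab_a,
        label_is=lab_i,
    )
    return WindowPair(analyte=win_a, internal_standard=win_i), truth


@dataclass(frozen=True)
class LabeledDataset:
    """A stack of simulated window pairs with truth labels.

    windows / labels have shape (n_samples, 2, 400); channel 0 is the analyte,
    channel 1 the internal standard.
    """

    windows: np.ndarray
    labels: np.ndarray
    concentrations: np.ndarray
    true_ratios: np.ndarray
    seed: int

    @property
    def n_samples(self) -> int:
        return self.windows.shape[0]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0] * 2

    @property
    def n_points(self) -> int:
        return int(np.prod(self.windows.shape))

    def flat_windows(self) -> np.ndarray:
        """(2 * n_samples, 400) view, analyte and IS interleaved per sample."""
        return self.windows.reshape(-1, WINDOW_LENGTH)

    def flat_labels(self) -> np.ndarray:
        return self.labels.reshape(-1, WINDOW_LENGTH)


def generate_dataset(
    n_samples: int,
    design: CalibrationDesign,
    shape_dist: ShapeDistribution,
    noise: NoiseModel,
    seed: int,
    mode: AcquisitionMode = AcquisitionMode.PARALLEL,
) -> LabeledDataset:
    """Generate ``n_samples`` labeled acquisitions (2 windows each).

    Per-sample concentration is drawn log-uniformly across the design's level
    range and shape parameters from ``shape_dist``.  Identical seeds yield
    bit-identical datasets.
    """
    seed = _require_seed(seed)
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = np.random.default_rng(seed)
    windows = np.zeros((n_samples, 2, WINDOW_LENGTH))
    labels = np.zeros((n_samples, 2, WINDOW_LENGTH), dtype=np.int8)
    concs = np.zeros(n_samples)
    ratios = np.zeros(n_samples)
    lo, hi = np.log(design.levels[0]), np.log(design.levels[-1])
    for i in range(n_samples):
        conc = float(np.exp(rng.uniform(lo, hi)))
        shape = shape_dist.draw(rng)
        child_seed = int(rng.integers(0, 2**63 - 1))
        pair, truth = simulate_window_pair(conc, design, shape, noise, mode, child_seed)
        windows[i, 0] = pair.analyte.intensities
        windows[i, 1] = pair.internal_standard.intensities
        labels[i, 0] = truth.label_analyte.mask
        labels[i, 1] = truth.label_is.mask
        concs[i] = conc
        ratios[i] = truth.true_ratio
    return LabeledDataset(
        windows=windows, labels=labels, concentrations=concs,
        true_ratios=ratios, seed=seed,
    )


def generate_calibration_run(
    design: CalibrationDesign,
    shape: PeakShapeParams,
    noise: NoiseModel,
    mode: AcquisitionMode,
    seed: int,
) -> list[tuple[float, WindowPair, SimTruth]]:
    """One WindowPair per level per replicate, in level-major order."""
    seed = _require_seed(seed)
    rng = np.random.default_rng(seed)
    out = []
    for conc in design.levels:
        for _ in range(design.replicates):
            child_seed = int(rng.integers(0, 2**63 - 1))
            pair, truth = simulate_window_pair(conc, design, shape, noise, mode, child_seed)
            out.append((conc, pair, truth))
    return out
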