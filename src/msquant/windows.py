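"""Fixed-window extraction, resampling, and label-vector construction.

Every downstream stage operates on a standard window: 400 intensity values
on a uniform 0.01 m/z grid spanning [center - 2, center + 2).  The grid is
left-closed / right-open so that the window length is exactly 400 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of points in a standard window.
WINDOW_LENGTH = 400

#: m/z spacing between adjacent grid points.
GRID_SPACING = 0.01

#: Half-width of the window in m/z units (two mass units on either side).
WINDOW_HALF_WIDTH = 2.0


class CoverageError(ValueError):
    """The input spectrum does not span the requested window."""


class AnnotationError(ValueError):
    """A peak annotation is malformed (e.g. left endpoint >= right)."""


def window_grid(center_mz: float) -> np.ndarray:
    """Return the standard 400-point m/z grid for ``center_mz``.

    Point ``k`` sits at ``center_mz - 2 + 0.01 * k`` for ``k = 0..399``.
    """
    return center_mz - WINDOW_HALF_WIDTH + GRID_SPACING * np.arange(WINDOW_LENGTH)


@dataclass(frozen=True)
class PeakWindow:
    """A resampled intensity window around a target fragment m/z.

    Attributes
    ----------
    center_mz:
        m/z of the target fragment ion.
    intensities:
        Length-400 vector of intensities on the standard grid.  Raw windows
        may contain any finite values (noise can dip below zero); area
        computation uses them unmodified.
    """

    center_mz: float
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (WINDOW_LENGTH,):
            raise ValueError(
                f"window must have exactly {WINDOW_LENGTH} points, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("window intensities must be finite")
        object.__setattr__(self, "intensities", arr)

    @property
    def grid_start(self) -> float:
        return self.center_mz - WINDOW_HALF_WIDTH

    @property
    def spacing(self) -> float:
        return GRID_SPACING

    @property
    def grid(self) -> np.ndarray:
        return window_grid(self.center_mz)


@dataclass(frozen=True)
class LabelVector:
    """A 0/1 peak-region mask aligned with a :class:`PeakWindow`."""

    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.shape != (WINDOW_LENGTH,):
            raise ValueError(
                f"label vector must have exactly {WINDOW_LENGTH} points, got {arr.shape}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("label vector entries must be 0 or 1")
        object.__setattr__(self, "mask", arr.astype(np.int8))

    @property
    def n_labeled(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PeakAnnotation:
    """Expert-style peak endpoints in m/z units."""

    left_mz: float
    right_mz: float

    def __post_init__(self) -> None:
        if not self.left_mz < self.right_mz:
            raise AnnotationError(
                f"left endpoint ({self.left_mz}) must be < right ({self.right_mz})"
            )


def resample_window(
    mz: np.ndarray, intensity: np.ndarray, center_mz: float
) -> PeakWindow:
    """Resample an (m/z, intensity) profile onto the standard window grid.

    Linear interpolation between profile points; the profile must cover the
    full window ``[center - 2, center + 2)``.

    Raises
    ------
    CoverageError
        If the profile does not span the window; the message names the
        missing range.
    ValueError
        If the profile m/z values are not strictly increasing.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.ndim != 1 or mz.size < 2 or mz.shape != intensity.shape:
        raise ValueError("profile must be two equal-length 1-D arrays with >= 2 points")
    if not np.all(np.diff(mz) > 0):
        raise ValueError("profile m/z values must be strictly increasing")
    grid = window_grid(center_mz)
    lo, hi = grid[0], grid[-1]
    if mz[0] > lo or mz[-1] < hi:
        missing = []
        if mz[0] > lo:
            missing.append(f"[{lo:.4f}, {min(mz[0], hi):.4f})")
        if mz[-1] < hi:
            missing.append(f"({max(mz[-1], lo):.4f}, {hi:.4f}]")
        raise CoverageError(
            f"spectrum does not cover window around m/z {center_mz}: "
            f"missing {' and '.join(missing)}"
        )
    return PeakWindow(center_mz=center_mz, intensities=np.interp(grid, mz, intensity))


def labels_from_annotation(ann: PeakAnnotation, window: PeakWindow) -> LabelVector:
    """Build the 0/1 mask for an annotation: grid points inside
    ``[left_mz, right_mz]`` (both endpoints inclusive) are labeled 1."""
    grid = window.grid
    mask = (grid >= ann.left_mz) & (grid <= ann.right_mz)
    return LabelVector(mask=mask.astype(np.int8))


def longest_run(mask: np.ndarray) -> np.ndarray:
    """Keep only the longest contiguous run of ones (leftmost on ties).

    Returns a new 0/1 array of the same length; all-zero input maps to
    all-zero output.
    """
    mask = np.asarray(mask).astype(np.int8)
    out = np.zeros_like(mask)
    padded = np.concatenate(([0], mask, [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        return out
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax keeps the leftmost maximum
    out[starts[best]: ends[best]] = 1
    return out
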