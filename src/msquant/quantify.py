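"""Peak-area integration and internal-standard ratio quantification.

The area of a labeled peak region is the masked dot product scaled by the
grid spacing::

    S = (x . y) * dm

with x the raw intensity vector, y the 0/1 mask, and dm = 0.01 m/z.  The
analyte/IS area ratio is the quantitative signal; a calibration line of
ratio versus spiked concentration back-calculates unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .windows import GRID_SPACING, LabelVector, PeakWindow


class QuantificationError(ValueError):
    """Quantification cannot proceed (zero IS area, degenerate fit, ...)."""


@dataclass(frozen=True)
class AreaResult:
    area: float
    n_points: int


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    levels: tuple
    drug_id: str = ""


@dataclass(frozen=True)
class QuantResult:
    ratio: float
    back_calc_conc: float
    bias_percent: float | None = None
    negative_flag: bool = False


def _as_array(x, name):
    if isinstance(x, PeakWindow):
        return x.intensities
    if isinstance(x, LabelVector):
        return x.mask
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return arr


def peak_area(window, mask, dm: float = GRID_SPACING) -> AreaResult:
    """Masked rectangle-rule area on raw intensities: ``sum(x * y) * dm``."""
    x = _as_array(window, "window")
    y = _as_array(mask, "mask")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: window {x.shape} vs mask {y.shape}")
    return AreaResult(area=float(np.dot(x, y) * dm), n_points=int(np.sum(y != 0)))


def area_ratio(analyte_area: AreaResult | float, is_area: AreaResult | float) -> float:
    """Analyte / internal-standard area ratio; zero IS area is an error, not NaN."""
    a = analyte_area.area if isinstance(analyte_area, AreaResult) else float(analyte_area)
    i = is_area.area if isinstance(is_area, AreaResult) else float(is_area)
    if i <= 0:
        raise QuantificationError(
            f"internal-standard area must be > 0 for ratio quantification, got {i}"
        )
    return a / i


def pair_ratio(pair, masks: tuple) -> float:
    """Ratio for a simulated :class:`~msquant.simulate.WindowPair` given
    (analyte mask, IS mask)."""
    mask_a, mask_i = masks
    return area_ratio(
        peak_area(pair.analyte, mask_a), peak_area(pair.internal_standard, mask_i)
    )


def fit_calibration(
    concs, ratios, drug_id: str = "", weighting: str = "none"
) -> CalibrationCurve:
    """Least-squares line of area ratio versus concentration.

    ``weighting='none'`` is ordinary least squares; ``'1/x'`` weights each
    point by the reciprocal of its concentration (common TDM practice).  R^2
    is the coefficient of determination of the (weighted) fit.
    """
    concs = np.asarray(concs, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if concs.shape != ratios.shape or concs.ndim != 1:
        raise ValueError("concs and ratios must be equal-length 1-D arrays")
    if np.unique(concs).size < 3:
        raise QuantificationError("calibration requires >= 3 distinct concentrations")
    if np.ptp(concs) == 0:
        raise QuantificationError("zero concentration variance")
    if weighting == "none":
        res = stats.linregress(concs, ratios)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue ** 2)
    elif weighting == "1/x":
        if np.any(concs <= 0):
            raise QuantificationError("1/x weighting requires positive concentrations")
        w = 1.0 / concs
        sw = w.sum()
        xbar = np.sum(w * concs) / sw
        ybar = np.sum(w * ratios) / sw
        sxx = np.sum(w * (concs - xbar) ** 2)
        sxy = np.sum(w * (concs - xbar) * (ratios - ybar))
        slope = float(sxy / sxx)
        intercept = float(ybar - slope * xbar)
        fitted = slope * concs + intercept
        ss_res = np.sum(w * (ratios - fitted) ** 2)
        ss_tot = np.sum(w * (ratios - ybar) ** 2)
        r2 = float(1.0 - ss_res / ss_tot)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        slope=slope, intercept=intercept, r_squared=r2,
        levels=tuple(np.unique(concs)), drug_id=drug_id,
    )


def back_calculate(
    ratio: float, curve: CalibrationCurve, nominal: float | None = None
) -> QuantResult:
    """Invert the calibration line: ``conc = (ratio - intercept) / slope``.

    Negative back-calculated concentrations are returned with a flag rather
    than clipped.
    """
    if curve.slope == 0:
        raise QuantificationError("calibration slope is zero; cannot back-calculate")
    conc = (ratio - curve.intercept) / curve.slope
    bias = None
    if nominal is not None:
        if nominal <= 0:
            raise ValueError("nominal concentration must be > 0 for bias")
        bias = 100.0 * (conc - nominal) / nominal
    return QuantResult(
        ratio=float(ratio), back_calc_conc=float(conc),
        bias_percent=bias, negative_flag=bool(conc < 0),
    )


def process_efficiency(ratio_processed: float, ratio_neat: float) -> float:
    """Percent recovery of the analyte/IS response ratio through the full
    sample process relative to neat solvent."""
    if ratio_neat <= 0:
        raise ValueError(f"neat-solvent ratio must be > 0, got {ratio_neat}")
    return 100.0 * ratio_processed / ratio_neat
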