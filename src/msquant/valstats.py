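"""Method-validation statistics: precision/accuracy, Pearson, Bland-Altman.

All standard deviations are sample (n-1) SDs; the 95% limits of agreement use
the conventional 1.96 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PrecisionAccuracyReport:
    mean: float
    rsd_percent: float
    bias_percent: float
    n: int


@dataclass(frozen=True)
class AgreementReport:
    mean_difference: float
    loa_low: float
    loa_high: float
    pearson_r: float
    means: np.ndarray
    differences: np.ndarray


def precision_accuracy(values, nominal: float) -> PrecisionAccuracyReport:
    """RSD (100*sd/mean) and bias (100*(mean-nominal)/nominal) of replicates."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("precision requires >= 2 replicate values")
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return PrecisionAccuracyReport(
        mean=mean,
        rsd_percent=100.0 * sd / mean,
        bias_percent=100.0 * (mean - nominal) / nominal,
        n=values.size,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("pearson_r requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r requires nonzero variance in both arguments")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(method_a, method_b) -> AgreementReport:
    """Agreement between two paired measurement series.

    Differences are a - b; limits of agreement are mean +/- 1.96 * sample SD.
    The per-pair (mean, difference) table is returned for plotting.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired series must match: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("bland_altman requires n >= 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    try:
        r = pearson_r(a, b)
    except ValueError:
        r = float("nan")
    return AgreementReport(
        mean_difference=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        pearson_r=r,
        means=(a + b) / 2.0,
        differences=diff,
    )
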