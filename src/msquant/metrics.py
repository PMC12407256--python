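"""Segmentation quality metrics: pooled confusion counts and area deviation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import peak_area


@dataclass(frozen=True)
class SegmentationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    area_ratio_deviation: float

    @property
    def n_points(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predictions: np.ndarray, references: np.ndarray):
    """Pooled point-level TP / FP / TN / FN over a stack of masks."""
    pred = np.asarray(predictions).astype(bool)
    ref = np.asarray(references).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    tp = int(np.sum(pred & ref))
    fp = int(np.sum(pred & ~ref))
    tn = int(np.sum(~pred & ~ref))
    fn = int(np.sum(~pred & ref))
    return tp, fp, tn, fn


def evaluate_segmentation(
    predictions: np.ndarray, references: np.ndarray, windows: np.ndarray
) -> SegmentationMetrics:
    """Score predicted masks against reference masks.

    ``predictions`` / ``references`` / ``windows``: equal-shape (N, L) stacks.
    Sensitivity, specificity, and accuracy are pooled over all points.  The
    area-ratio deviation is the mean of ``|predicted_area / reference_area - 1|``
    over peaks whose reference area is positive, with both areas computed from
    the same raw window intensities.
    """
    pred = np.atleast_2d(np.asarray(predictions))
    ref = np.atleast_2d(np.asarray(references))
    win = np.atleast_2d(np.asarray(windows, dtype=float))
    if not (pred.shape == ref.shape == win.shape):
        raise ValueError(
            f"shape mismatch: predictions {pred.shape}, references {ref.shape}, "
            f"windows {win.shape}"
        )
    tp, fp, tn, fn = confusion_counts(pred, ref)
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    acc = (tp + tn) / total if total > 0 else float("nan")
    devs = []
    for p, r, w in zip(pred, ref, win):
        ref_area = peak_area(w, r).area
        if ref_area > 0:
            devs.append(abs(peak_area(w, p).area / ref_area - 1.0))
    dev = float(np.mean(devs)) if devs else 0.0
    return SegmentationMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        area_ratio_deviation=dev,
    )
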