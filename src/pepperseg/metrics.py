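"""Segmentation metrics and first-layer kernel-importance analysis.

Binary pepper/background segmentation is scored with mean intersection over
union (mIoU) and the pepper-class F1.  Dataset-level scores aggregate pixel
confusion counts over all images (additivity), rather than averaging
per-image metrics; a per-image view is available for inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion_counts", "mean_iou", "f1_score",
           "kernel_importance"]


@dataclass
class ConfusionCounts:
    """2x2 pixel tally; p[i, j] = pixels of true class i predicted class j.

    Class order: 0 = non-pepper, 1 = pepper.
    """

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.int64)
        if self.p.shape != (2, 2) or self.p.min() < 0:
            raise ValueError("confusion counts must be a non-negative 2x2 matrix")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.p + other.p)

    @property
    def total(self) -> int:
        return int(self.p.sum())


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask.values if hasattr(mask, "values") else mask)
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("masks must be binary (0/1)")
    return arr.astype(np.int64)


def confusion_counts(pred_mask, truth_mask) -> ConfusionCounts:
    """Exact pixel tally of a predicted vs true binary mask."""
    pred = _as_binary(pred_mask)
    truth = _as_binary(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, truth {truth.shape}")
    p = np.bincount(truth.ravel() * 2 + pred.ravel(), minlength=4).reshape(2, 2)
    return ConfusionCounts(p)


def mean_iou(counts: ConfusionCounts) -> float:
    """Mean over classes of p_ii / (t_i + sum_j p_ji - p_ii).

    A class absent from both truth and prediction is skipped and the mean
    renormalized (avoids 0/0 on images without peppers).
    """
    p = counts.p
    ious = []
    for i in range(2):
        denom = p[i, :].sum() + p[:, i].sum() - p[i, i]
        if denom == 0:
            continue
        ious.append(p[i, i] / denom)
    if not ious:
        raise ValueError("no class present in either mask")
    return float(np.mean(ious))


def f1_score(counts: ConfusionCounts) -> float:
    """Pepper-class F1 = harmonic mean of precision and recall."""
    tp = counts.p[1, 1]
    fp = counts.p[0, 1]
    fn = counts.p[1, 0]
    if tp == 0:
        if fp == 0 and fn == 0:
            warnings.warn("no positives in truth or prediction; F1 defined as 0")
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))


def kernel_importance(first_layer_weights: np.ndarray,
                      n_channels: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """L1 kernel importance of each input channel of the first conv layer.

    Adopts the filter-pruning statistic: for input channel c,
    ``score[c] = sum over kernels and spatial taps of |weight[k, c, :, :]|``.
    Returns ``(scores, per_kernel)`` where per_kernel[k, c] is the breakdown
    by output kernel.  Bias terms are excluded (the convs feeding batch norm
    carry no bias).
    """
    w = np.asarray(first_layer_weights, dtype=np.float64)
    if w.ndim != 4 or w.shape[1] != n_channels:
        raise ValueError(f"expected (kernels, {n_channels}, kh, kw) weights, got {w.shape}")
    per_kernel = np.abs(w).sum(axis=(2, 3))
    return per_kernel.sum(axis=0), per_kernel
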