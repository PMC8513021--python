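"""Color-ratio chromaticity maps and the 12-channel segmentation input.

Nine per-pixel ratios of the simulated R, G, B intensities augment the raw
channels before segmentation.  Ratios are invariant to per-pixel intensity
scaling, so they suppress the illumination and shading variation that
dominates field imagery while preserving chromatic contrast:

    d1 = G/(R+G+B)   d2 = R/(R+G+B)   d3 = B/(R+G+B)      (normalized RGB)
    d4 = G/(G+B)     d5 = G/(G+R)     d6 = B/(B+R)
    d7 = B/(G+B)     d8 = R/(G+R)     d9 = R/(R+B)        (pairwise ratios)

The channel order of the assembled stack is fixed and documented as
(R, G, B, d1 ... d9) so that kernel-importance indices are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .optics import SensorImage, DEFAULT_EPSILON

__all__ = ["CHANNEL_NAMES", "compute_ratio_maps", "assemble_feature_stack"]

CHANNEL_NAMES = ("R", "G", "B", "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9")


def _floor(x, eps: float):
    """max(x, eps) for either ndarray or autodiff Tensor denominators."""
    if isinstance(x, Tensor):
        return x.clamp_min(eps)
    return np.maximum(x, eps)


def _ratio_planes(r, g, b, eps: float):
    """The nine ratio formulas; generic over ndarray and Tensor operands.

    Denominators are floored at eps as a defensive guard; with an eps-floored
    sensor image the floor is never active.
    """
    total = _floor(r + g + b, eps)
    d1 = g / total
    d2 = r / total
    d3 = b / total
    gb = _floor(g + b, eps)
    gr = _floor(g + r, eps)
    br = _floor(b + r, eps)
    rb = _floor(r + b, eps)
    d4 = g / gb
    d5 = g / gr
    d6 = b / br
    d7 = b / gb
    d8 = r / gr
    d9 = r / rb
    return [d1, d2, d3, d4, d5, d6, d7, d8, d9]


def compute_ratio_maps(sensor: SensorImage) -> np.ndarray:
    """Return the nine ratio planes as a (9, H, W) array in order d1..d9."""
    ch = sensor.channels
    if not np.all(np.isfinite(ch)):
        bad = tuple(int(v) for v in np.argwhere(~np.isfinite(ch))[0])
        raise ValueError(f"non-finite sensor value at (channel, row, col) = {bad}")
    r, g, b = ch[0], ch[1], ch[2]
    return np.stack(_ratio_planes(r, g, b, sensor.epsilon))


def assemble_feature_stack(sensor: SensorImage, ratios: np.ndarray | None = None,
                           use_ratios: bool = True) -> np.ndarray:
    """Concatenate RGB and ratio planes into the (12, H, W) network input.

    With ``use_ratios=False`` only the 3 RGB planes are returned — the input
    of the filter-only and no-filter baseline arms.
    """
    if not use_ratios:
        return sensor.channels.copy()
    if ratios is None:
        ratios = compute_ratio_maps(sensor)
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.shape != (9,) + sensor.channels.shape[1:]:
        raise ValueError("ratio planes must be (9, H, W) matching the sensor image")
    return np.concatenate([sensor.channels, ratios], axis=0)


def feature_stack_t(sensor: Tensor, epsilon: float = DEFAULT_EPSILON,
                    use_ratios: bool = True) -> Tensor:
    """Differentiable feature assembly for a (B, 3, H, W) sensor batch."""
    if not use_ratios:
        return sensor
    r = sensor[:, 0:1]
    g = sensor[:, 1:2]
    b = sensor[:, 2:3]
    return concat([sensor] + _ratio_planes(r, g, b, epsilon), axis=1)
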