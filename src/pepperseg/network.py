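"""U-Net-like encoder-decoder for per-pixel pepper/background probability.

Encoder: five blocks of (3x3 conv - batch norm - ReLU) x 2 with 2x2 stride-2
max pools between them; channel widths b, 2b, 4b, 8b, 8b for base width b.
Decoder: four 2x2 stride-2 transposed-conv upsamplings, each concatenated with
the matching encoder feature map (skip connection) and followed by a double
conv block; a final 1x1 convolution and sigmoid yield the probability map.

At the reference width b = 64 and a 256x256x12 input the bottleneck is
16x16x512 and the output 256x256x1.  Width scales proportionally so the same
architecture trains at desk scale (b = 8, 64x64 inputs).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Module, max_pool_2x2

__all__ = ["GroundTruthMask", "UNet", "build_network", "shape_trace",
           "bce_loss", "total_loss"]


class GroundTruthMask:
    """Per-pixel binary label map; 1 = pepper, 0 = background."""

    def __init__(self, values):
        arr = np.asarray(values)
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


class DoubleConv(Module):
    """(conv 3x3 pad 1 -> BN -> ReLU) x 2."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class UNet(Module):
    def __init__(self, in_channels: int, base_width: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        b = base_width
        self.in_channels = in_channels
        self.base_width = b
        self.enc1 = DoubleConv(in_channels, b, rng)
        self.enc2 = DoubleConv(b, 2 * b, rng)
        self.enc3 = DoubleConv(2 * b, 4 * b, rng)
        self.enc4 = DoubleConv(4 * b, 8 * b, rng)
        self.enc5 = DoubleConv(8 * b, 8 * b, rng)
        self.up1 = ConvTranspose2x2(8 * b, 8 * b, rng)
        self.dec1 = DoubleConv(16 * b, 4 * b, rng)
        self.up2 = ConvTranspose2x2(4 * b, 4 * b, rng)
        self.dec2 = DoubleConv(8 * b, 2 * b, rng)
        self.up3 = ConvTranspose2x2(2 * b, 2 * b, rng)
        self.dec3 = DoubleConv(4 * b, b, rng)
        self.up4 = ConvTranspose2x2(b, b, rng)
        self.dec4 = DoubleConv(2 * b, b, rng)
        self.outconv = Conv2d(b, 1, kernel=1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("spatial size must be divisible by 16 (four pooling stages)")
        e1 = self.enc1(x)
        e2 = self.enc2(max_pool_2x2(e1))
        e3 = self.enc3(max_pool_2x2(e2))
        e4 = self.enc4(max_pool_2x2(e3))
        e5 = self.enc5(max_pool_2x2(e4))
        d1 = self.dec1(concat([self.up1(e5), e4], axis=1))
        d2 = self.dec2(concat([self.up2(d1), e3], axis=1))
        d3 = self.dec3(concat([self.up3(d2), e2], axis=1))
        d4 = self.dec4(concat([self.up4(d3), e1], axis=1))
        return self.outconv(d4).sigmoid()


def build_network(in_channels: int, base_width: int = 64,
                  seed: int | None = None) -> UNet:
    """Construct the segmentation network (12 channels with ratio maps, 3 without)."""
    if in_channels not in (3, 12):
        raise ValueError("in_channels must be 3 (RGB only) or 12 (RGB + ratio maps)")
    rng = np.random.default_rng(seed)
    return UNet(in_channels, base_width, rng)


def shape_trace(in_channels: int, base_width: int, height: int, width: int):
    """Arithmetic walk of the layer list: [(layer name, (H, W, C)), ...].

    Mirrors the reference table at base_width 64 / 256x256x12 input
    (bottleneck block5 = 16x16x512, output 256x256x1).
    """
    if height % 16 or width % 16:
        raise ValueError("spatial size must be divisible by 16")
    b = base_width
    h, w = height, width
    rows = [("input", (h, w, in_channels))]
    enc_widths = [b, 2 * b, 4 * b, 8 * b, 8 * b]
    for i, c in enumerate(enc_widths, start=1):
        rows.append((f"block{i}", (h, w, c)))
        if i < 5:
            h, w = h // 2, w // 2
            rows.append((f"pool{i}", (h, w, c)))
    # decoder: upsample + skip concat, then double conv
    skip = [8 * b, 4 * b, 2 * b, b]
    out_c = [4 * b, 2 * b, b, b]
    c = enc_widths[-1]
    for i in range(4):
        h, w = h * 2, w * 2
        rows.append((f"upsampling{i + 1}", (h, w, c + skip[i])))
        c = out_c[i]
        rows.append((f"block{i + 6}", (h, w, c)))
    rows.append(("outconv", (h, w, 1)))
    return rows


# ------------------------------------------------------------------- losses

_CLIP = 1e-12  # numerical guard inside the logs


def bce_loss(pred, truth):
    """Mean binary cross-entropy between a probability map and a binary mask.

    ``pred`` may be a plain array or an autodiff Tensor (differentiable path).
    The mean reduction keeps the smoothness-weight grid comparable across
    image and batch sizes.
    """
    truth_arr = np.asarray(truth.values if hasattr(truth, "values") else truth,
                           dtype=np.float64)
    if not np.all((truth_arr == 0) | (truth_arr == 1)):
        raise ValueError("ground truth must be binary")
    pred_shape = pred.shape
    if np.prod(pred_shape) != truth_arr.size:
        raise ValueError(f"shape mismatch: pred {pred_shape}, truth {truth_arr.shape}")
    if isinstance(pred, Tensor):
        t = Tensor(truth_arr.reshape(pred_shape))
        p = pred.clip(_CLIP, 1.0 - _CLIP)
        return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    p = np.clip(np.asarray(pred, dtype=np.float64).reshape(truth_arr.shape),
                _CLIP, 1.0 - _CLIP)
    return float(-(truth_arr * np.log(p) + (1 - truth_arr) * np.log(1 - p)).mean())


def total_loss(bce, smooth, eta: float):
    """Combined objective: segmentation BCE plus eta * curve smoothness."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    return bce + eta * smooth
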