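"""Differentiable forward model from hyperspectral radiance to a simulated RGB image.

The image formation chain is

    radiance cube  --(per-band transmittance T)-->  filtered radiance
                   --(camera spectral response C)-->  raw RGB intensities
                   --(normalize, clip, epsilon floor)-->  sensor image in [eps, 1]

The transmittance curve is the design variable: one non-negative weight per
spectral band, mathematically a 1x1 depth-wise convolution applied identically
at every pixel.  The camera spectral response (CSR) is a frozen 3 x N matrix,
the 1x1 convolution with three kernels.  All three steps are differentiable so
a segmentation loss can be back-propagated into the filter weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, channel_project

__all__ = [
    "GridMismatchError",
    "ConfigurationError",
    "SpectralCube",
    "TransmittanceCurve",
    "CameraResponse",
    "SensorImage",
    "default_band_grid",
    "apply_filter",
    "sense_rgb",
    "normalize_and_clip",
    "estimate_normalization_bounds",
    "gaussian_csr",
    "initial_filter",
    "load_csr_csv",
    "save_transmittance_csv",
    "load_transmittance_csv",
]

DEFAULT_EPSILON = 0.01


class GridMismatchError(ValueError):
    """Two spectral objects do not share the same wavelength grid."""


class ConfigurationError(ValueError):
    """Invalid normalization or filter configuration."""


def default_band_grid(n_bands: int = 103, lo: float = 400.0, hi: float = 700.0) -> np.ndarray:
    """Uniform band centers over the visible range (default 103 bands, 400-700 nm)."""
    return np.linspace(lo, hi, n_bands)


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=np.float64)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("wavelengths must be a non-empty 1-D array")
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return w


@dataclass
class SpectralCube:
    """Radiance on a (row, col, band) grid with an explicit wavelength axis."""

    values: np.ndarray  # (H, W, N), non-negative radiance
    wavelengths: np.ndarray  # (N,), nm, strictly increasing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = _check_wavelengths(self.wavelengths)
        if self.values.ndim != 3:
            raise ValueError("cube values must be (rows, cols, bands)")
        if self.values.shape[2] != self.wavelengths.size:
            raise GridMismatchError(
                f"cube has {self.values.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite radiance values")
        if self.values.min() < 0:
            raise ValueError("radiance must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class TransmittanceCurve:
    """One dimensionless transmittance weight per band; the learnable filter."""

    weights: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.wavelengths = _check_wavelengths(self.wavelengths)
        if self.weights.shape != self.wavelengths.shape:
            raise GridMismatchError("weights and wavelengths must have equal length")
        if self.weights.min() < 0:
            raise ValueError("transmittance weights must be non-negative")

    def rescaled_to_unit_peak(self) -> "TransmittanceCurve":
        """Export helper: scale so the maximum transmittance is 1 (fabrication)."""
        peak = self.weights.max()
        if peak <= 0:
            return TransmittanceCurve(self.weights.copy(), self.wavelengths)
        return TransmittanceCurve(self.weights / peak, self.wavelengths)


@dataclass
class CameraResponse:
    """3 x N per-channel sensitivities, rows ordered (R, G, B)."""

    sensitivities: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.sensitivities = np.asarray(self.sensitivities, dtype=np.float64)
        self.wavelengths = _check_wavelengths(self.wavelengths)
        if self.sensitivities.shape != (3, self.wavelengths.size):
            raise GridMismatchError("CSR must be a 3 x n_bands matrix on the band grid")
        if self.sensitivities.min() < 0:
            raise ValueError("CSR sensitivities must be non-negative")
        if np.any(self.sensitivities.max(axis=1) <= 0):
            raise ValueError("each CSR channel needs at least one positive entry")


@dataclass
class SensorImage:
    """Simulated 3-channel camera output; every value lies in [epsilon, 1]."""

    channels: np.ndarray  # (3, H, W)
    norm_min: float
    norm_max: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("sensor image must be (3, H, W)")
        if self.norm_max <= self.norm_min:
            raise ConfigurationError("norm_max must exceed norm_min")


def _same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size or not np.allclose(a, b):
        raise GridMismatchError("wavelength grids differ")


# --------------------------------------------------------------------- ops

def apply_filter(cube: SpectralCube, filt: TransmittanceCurve) -> SpectralCube:
    """Wavelength-wise product L(x, y, lam) = R(x, y, lam) * T(lam).

    Spatially invariant: the same per-band scale at every pixel.
    """
    _same_grid(cube.wavelengths, filt.wavelengths)
    return SpectralCube(cube.values * filt.weights[None, None, :], cube.wavelengths)


def sense_rgb(cube: SpectralCube, csr: CameraResponse) -> np.ndarray:
    """Project filtered radiance onto R, G, B: P_k = sum_i C_k(lam_i) L(lam_i).

    Returns the raw (3, H, W) intensities before normalization.
    """
    _same_grid(cube.wavelengths, csr.wavelengths)
    return np.einsum("kn,hwn->khw", csr.sensitivities, cube.values, optimize=True)


def normalize_and_clip(raw: np.ndarray, norm_min: float, norm_max: float,
                       epsilon: float = DEFAULT_EPSILON) -> SensorImage:
    """Scale raw intensities to [0, 1], clip, then floor at epsilon.

    The scaled value (raw - min) / (max - min) is clipped to [0, 1] to emulate
    sensor saturation and dark current, then epsilon is added and the result
    re-capped at 1.  The floor guarantees strictly positive channels so the
    color-ratio denominators can never vanish.
    """
    if norm_max <= norm_min:
        raise ConfigurationError("norm_max must exceed norm_min")
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    raw = np.asarray(raw, dtype=np.float64)
    scaled = (raw - norm_min) / (norm_max - norm_min)
    out = np.minimum(np.clip(scaled, 0.0, 1.0) + epsilon, 1.0)
    return SensorImage(out, norm_min, norm_max, epsilon)


def normalize_and_clip_t(raw: Tensor, norm_min, norm_max,
                         epsilon: float = DEFAULT_EPSILON) -> Tensor:
    """Differentiable version of :func:`normalize_and_clip` for training graphs.

    ``norm_min``/``norm_max`` may be scalars (global normalization, the
    default) or length-3 arrays for the per-channel mode, broadcast against
    the (B, 3, H, W) raw batch.
    """
    mn = np.asarray(norm_min, dtype=np.float64)
    mx = np.asarray(norm_max, dtype=np.float64)
    if np.any(mx <= mn):
        raise ConfigurationError("norm_max must exceed norm_min")
    if mn.ndim == 1:
        mn = mn[None, :, None, None]
        mx = mx[None, :, None, None]
    scaled = (raw - mn) * (1.0 / (mx - mn))
    return (scaled.clip(0.0, 1.0) + epsilon).clamp_max(1.0)


def sense_batch_t(cube_batch: Tensor, weights: Tensor, csr: CameraResponse) -> Tensor:
    """Filter + CSR for a (B, N, H, W) batch inside an autodiff graph."""
    n = csr.sensitivities.shape[1]
    filtered = cube_batch * weights.reshape(1, n, 1, 1)
    return channel_project(filtered, csr.sensitivities)


def estimate_normalization_bounds(cubes, csr: CameraResponse,
                                  filt: TransmittanceCurve | None = None,
                                  low_pct: float = 0.1,
                                  high_pct: float = 99.9,
                                  per_channel: bool = False):
    """Percentile-based (min, max) of raw sensed values over a set of cubes.

    The normalization constants of the sensor simulation are dataset
    properties; this estimates them from the training cubes under the given
    (typically initial) filter.  Global by default (one min/max shared by all
    three channels); ``per_channel=True`` returns length-3 arrays instead.
    """
    cubes = list(cubes)
    if not cubes:
        raise ValueError("need at least one cube to estimate normalization bounds")
    if not (0 <= low_pct < high_pct <= 100):
        raise ConfigurationError("percentiles must satisfy 0 <= low < high <= 100")
    values = []
    for cube in cubes:
        filtered = cube if filt is None else apply_filter(cube, filt)
        raw = sense_rgb(filtered, csr)
        values.append(raw.reshape(3, -1))
    allv = np.concatenate(values, axis=1)
    if per_channel:
        lo = np.percentile(allv, low_pct, axis=1)
        hi = np.percentile(allv, high_pct, axis=1)
        return lo, hi
    lo, hi = np.percentile(allv, [low_pct, high_pct])
    return float(lo), float(hi)


# ----------------------------------------------------------- construction

def gaussian_csr(wavelengths: np.ndarray, peaks=(610.0, 540.0, 465.0),
                 sigma: float = 30.0) -> CameraResponse:
    """Default camera response: three unit-peak Gaussian sensitivity curves.

    Typical silicon RGB sensor behaviour (R peaking ~610 nm, G ~540 nm,
    B ~465 nm); replace with a measured curve via :func:`load_csr_csv` when
    available.
    """
    w = _check_wavelengths(wavelengths)
    sens = np.stack([np.exp(-0.5 * ((w - p) / sigma) ** 2) for p in peaks])
    return CameraResponse(sens, w)


def initial_filter(wavelengths: np.ndarray, rng: np.random.Generator,
                   level: float = 0.5, jitter: float = 0.05) -> TransmittanceCurve:
    """Symmetric, strictly positive starting curve: level + U(-jitter, jitter)."""
    w = _check_wavelengths(wavelengths)
    weights = level + rng.uniform(-jitter, jitter, size=w.size)
    return TransmittanceCurve(np.maximum(weights, 1e-6), w)


# ------------------------------------------------------------------ CSV IO

def load_csr_csv(path, wavelengths: np.ndarray) -> CameraResponse:
    """Read a `wavelength_nm,R,G,B` table and interpolate onto the band grid."""
    w = _check_wavelengths(wavelengths)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"wavelength_nm", "R", "G", "B"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"CSR CSV needs columns {sorted(required)}")
        for row in reader:
            rows.append((float(row["wavelength_nm"]), float(row["R"]),
                         float(row["G"]), float(row["B"])))
    rows.sort()
    table = np.array(rows)
    sens = np.stack([np.interp(w, table[:, 0], table[:, k]) for k in (1, 2, 3)])
    return CameraResponse(sens, w)


def save_transmittance_csv(curve: TransmittanceCurve, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "transmittance"])
        for lam, t in zip(curve.wavelengths, curve.weights):
            writer.writerow([f"{lam:.10g}", f"{t:.10g}"])


def load_transmittance_csv(path) -> TransmittanceCurve:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = [(float(r["wavelength_nm"]), float(r["transmittance"])) for r in reader]
    rows.sort()
    table = np.array(rows)
    return TransmittanceCurve(table[:, 1], table[:, 0])
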