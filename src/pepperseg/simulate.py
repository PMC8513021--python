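"""Synthetic hyperspectral greenhouse scenes with known spectral contrast.

Real pepper/leaf scenes are spectrally hard: both classes are green, and the
discriminative information is a narrow-band difference in reflectance
(hypothesized to stem from differing chlorophyll a/b content, with a
chlorophyll-b absorption feature just below 650 nm).  The simulator
reproduces exactly that structure with full ground truth:

* both classes share one smooth green-vegetation reflectance template
  (low blue, peak near 550 nm, absorption dip near 650 nm);
* inside a configurable contrast window the pepper reflectance is scaled by
  (1 + contrast_delta) — the *only* systematic class difference;
* radiance = illumination(lambda) x reflectance(class, lambda)
  x shading(y, x) x multiplicative noise, so per-pixel intensity varies the
  way inconstant natural illumination does while chromaticity does not.

Because the discriminative window is known, a learned transmittance curve can
be checked against it: the co-design succeeds if it transmits the window and
suppresses the rest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .network import GroundTruthMask
from .optics import SpectralCube

__all__ = ["SceneSpec", "make_endmember_spectra", "illumination_spectrum",
           "simulate_scene", "simulate_dataset"]


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic greenhouse scene."""

    n_bands: int = 60
    wl_lo: float = 400.0
    wl_hi: float = 700.0
    height: int = 64
    width: int = 64
    contrast_window: tuple = (630.0, 660.0)
    contrast_delta: float = 0.3
    illum_temperature: float = 5500.0  # K, daylight-like smooth SPD
    illum_scale: float = 1.0
    shading_amp: float = 0.25  # relative amplitude of the spatial shading field
    n_shapes: tuple = (3, 6)  # inclusive range of pepper-ellipse counts
    axis_range: tuple = (5.0, 12.0)  # ellipse semi-axis range, px
    noise_sd: float = 0.02  # per pixel-band multiplicative (log-normal) noise
    white_reference: bool = False  # stamp a reflectance-1 patch (mask 0)
    seed: int = 0

    def __post_init__(self):
        if self.contrast_delta < 0:
            raise ValueError("contrast_delta must be non-negative")
        lo, hi = self.contrast_window
        if not (self.wl_lo <= lo < hi <= self.wl_hi):
            raise ValueError("contrast window must lie inside the wavelength range")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_lo, self.wl_hi, self.n_bands)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _gauss(w, mu, sigma):
    return np.exp(-0.5 * ((w - mu) / sigma) ** 2)


def _green_template(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth green-vegetation reflectance: low blue, ~550 nm peak, ~650 nm dip."""
    w = wavelengths
    base = 0.05 + 0.32 * _gauss(w, 550.0, 50.0) + 0.10 * _gauss(w, 710.0, 60.0)
    return base * (1.0 - 0.30 * _gauss(w, 650.0, 15.0))


def make_endmember_spectra(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """(pepper, leaf) per-band reflectances; identical outside the window."""
    w = spec.wavelengths
    leaf = _green_template(w)
    lo, hi = spec.contrast_window
    window = (w >= lo) & (w <= hi)
    pepper = leaf * np.where(window, 1.0 + spec.contrast_delta, 1.0)
    if pepper.max() > 1.0:
        raise ValueError("contrast_delta pushes pepper reflectance above 1")
    return pepper, leaf


def illumination_spectrum(spec: SceneSpec) -> np.ndarray:
    """Blackbody-shaped spectral power distribution, normalized to mean 1."""
    w = spec.wavelengths
    c2 = 1.4388e7  # nm K
    spd = w ** -5 / np.expm1(c2 / (w * spec.illum_temperature))
    return spec.illum_scale * spd / spd.mean()


def _shading_field(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive spatial field: 1 + amp * (sum of low-freq plane waves)."""
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    s = np.zeros((spec.height, spec.width))
    for _ in range(2):
        theta = rng.uniform(0, 2 * np.pi)
        period = rng.uniform(0.7, 1.5) * max(spec.height, spec.width)
        phase = rng.uniform(0, 2 * np.pi)
        k = 2 * np.pi / period
        s += np.cos(k * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
    s /= 2.0
    return np.maximum(1.0 + spec.shading_amp * s, 0.05)


def _stamp_ellipses(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    n = int(rng.integers(spec.n_shapes[0], spec.n_shapes[1] + 1))
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    for _ in range(n):
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        a = rng.uniform(*spec.axis_range)
        b = rng.uniform(*spec.axis_range)
        theta = rng.uniform(0, np.pi)
        dx, dy = xx - cx, yy - cy
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        mask[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1
    return mask


def simulate_scene(spec: SceneSpec, rng: np.random.Generator,
                   return_components: bool = False):
    """One labeled scene: (SpectralCube, GroundTruthMask).

    With ``return_components=True`` also returns (illumination, shading) so the
    radiance factorization can be inverted exactly in checks.
    """
    pepper, leaf = make_endmember_spectra(spec)
    illum = illumination_spectrum(spec)
    shading = _shading_field(spec, rng)
    mask = _stamp_ellipses(spec, rng)

    refl = np.where(mask[:, :, None] == 1, pepper[None, None, :], leaf[None, None, :])
    if spec.white_reference:
        h8, w8 = max(spec.height // 8, 2), max(spec.width // 8, 2)
        refl[:h8, :w8, :] = 1.0
        mask[:h8, :w8] = 0
    radiance = illum[None, None, :] * refl * shading[:, :, None]
    if spec.noise_sd > 0:
        z = rng.standard_normal(radiance.shape)
        # mean-one log-normal multiplicative noise
        radiance = radiance * np.exp(spec.noise_sd * z - 0.5 * spec.noise_sd ** 2)

    cube = SpectralCube(radiance, spec.wavelengths)
    gt = GroundTruthMask(mask)
    if return_components:
        return cube, gt, illum, shading
    return cube, gt


def simulate_dataset(n_train: int, n_val: int, n_test: int, spec: SceneSpec,
                     seed: int, out_dir=None):
    """Generate disjoint train/val/test scene lists (optionally written to disk).

    Each image gets its own child seed, so the dataset is reproducible
    byte-for-byte from (spec, seed).  When ``out_dir`` is given, cubes are
    written as ENVI pairs, masks as 8-bit PNGs, plus a JSON manifest; the
    return value is then the manifest.  Without ``out_dir`` the in-memory
    scenes are returned as a dict of split -> list of (cube, mask).
    """
    if min(n_train, n_val, n_test) <= 0:
        raise ValueError("split sizes must be positive")
    counts = {"train": n_train, "val": n_val, "test": n_test}
    children = iter(np.random.SeedSequence(seed).spawn(n_train + n_val + n_test))
    scenes = {name: [simulate_scene(spec, np.random.default_rng(next(children)))
                     for _ in range(k)]
              for name, k in counts.items()}
    if out_dir is None:
        return scenes

    from . import io as pio  # local import: io pulls in Pillow

    return pio.write_dataset(scenes, spec, seed, out_dir)
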