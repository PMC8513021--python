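"""Dataset layout on disk: ENVI cubes, PNG masks, JSON manifests.

All writes are atomic (temp file + rename) so an interrupted run never leaves
a corrupt manifest or half-written cube behind.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .envi import read_envi, write_envi
from .network import GroundTruthMask
from .simulate import SceneSpec

__all__ = ["read_mask", "write_mask", "Manifest", "write_dataset",
           "load_dataset", "atomic_write_text"]


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def read_mask(path) -> GroundTruthMask:
    """Read an 8-bit single-channel PNG; pixels > 127 become pepper (1)."""
    img = Image.open(path)
    if img.mode != "L":
        raise ValueError(
            f"{path}: expected an 8-bit single-channel mask (mode 'L'), got mode "
            f"'{img.mode}'. Convert with e.g. Image.open(p).convert('L') only if "
            "the channels are known to be identical."
        )
    arr = np.asarray(img)
    return GroundTruthMask((arr > 127).astype(np.uint8))


def write_mask(mask: GroundTruthMask, path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    path = Path(path)
    arr = (mask.values * 255).astype(np.uint8)
    tmp = path.with_name(path.name + ".tmp.png")
    Image.fromarray(arr, mode="L").save(tmp, format="PNG")
    os.replace(tmp, path)


@dataclass
class Manifest:
    """Index of a dataset directory: split -> [(cube header, mask png)]."""

    splits: dict
    wavelengths: np.ndarray
    seed: int
    spec_hash: str
    root: Path

    def save(self, path) -> None:
        payload = {
            "splits": {k: [[str(c), str(m)] for c, m in v] for k, v in self.splits.items()},
            "wavelengths": [float(w) for w in self.wavelengths],
            "seed": self.seed,
            "spec_hash": self.spec_hash,
        }
        atomic_write_text(path, json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "Manifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        splits = {k: [(Path(c), Path(m)) for c, m in v] for k, v in payload["splits"].items()}
        mf = cls(splits=splits, wavelengths=np.array(payload["wavelengths"]),
                 seed=payload["seed"], spec_hash=payload["spec_hash"], root=path.parent)
        for pairs in mf.splits.values():
            for cube_path, mask_path in pairs:
                for p in (mf.root / cube_path, mf.root / mask_path):
                    if not p.exists():
                        raise FileNotFoundError(f"manifest references missing file {p}")
        return mf


def write_dataset(scenes: dict, spec: SceneSpec, seed: int, out_dir) -> Manifest:
    """Write split -> [(cube, mask)] scenes as ENVI + PNG + manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    splits = {}
    for split, pairs in scenes.items():
        entries = []
        for i, (cube, mask) in enumerate(pairs):
            stem = f"{split}_{i:03d}"
            hdr = out_dir / f"{stem}.hdr"
            png = out_dir / f"{stem}_mask.png"
            write_envi(cube, hdr)
            write_mask(mask, png)
            entries.append((Path(hdr.name), Path(png.name)))
        splits[split] = entries
    manifest = Manifest(splits=splits, wavelengths=spec.wavelengths, seed=seed,
                        spec_hash=spec.hash(), root=out_dir)
    manifest.save(out_dir / "manifest.json")
    return manifest


def load_dataset(manifest_or_dir, band_range=None) -> dict:
    """Load every split of a dataset directory into (cube, mask) pairs."""
    path = Path(manifest_or_dir)
    if path.is_dir():
        path = path / "manifest.json"
    manifest = Manifest.load(path)
    out = {}
    for split, pairs in manifest.splits.items():
        out[split] = [(read_envi(manifest.root / c, band_range=band_range),
                       read_mask(manifest.root / m)) for c, m in pairs]
    return out
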