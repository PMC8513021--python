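"""Minimal ENVI hyperspectral cube reader/writer.

ENVI files are a plain-text header (``.hdr``) describing a raw binary cube.
Only what hyperspectral field cameras actually emit is supported: BIL/BIP/BSQ
interleaves, float32/float64 samples, little/big endian, and a wavelength
list in nanometers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .optics import SpectralCube

__all__ = ["read_envi", "write_envi"]

_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            buf = [val]
            in_braces = True
        else:
            fields[key] = val
    return fields


def read_envi(header_path, band_range: tuple[float, float] | None = (400.0, 700.0)) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    ``band_range`` restricts the cube to the given wavelength window (default
    the visible 400-700 nm); pass ``None`` to keep all bands.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].strip().lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(tok) for tok in wl_text.replace("\n", " ").split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise ValueError(f"header lists {wavelengths.size} wavelengths for {bands} bands")
    if dtype_code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))

    data_path = header_path.with_suffix(".raw")
    if not data_path.exists():
        for ext in (".img", ".dat", ".bil", ".bsq", ".bip", ""):
            cand = header_path.with_suffix(ext)
            if cand != header_path and cand.exists():
                data_path = cand
                break
        else:
            raise FileNotFoundError(f"no binary companion found for {header_path}")

    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(f"{data_path} holds {raw.size} values, expected {expected} "
                         "(truncated or wrong header?)")
    if interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    elif interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    cube = np.ascontiguousarray(cube, dtype=np.float64)

    if band_range is not None:
        keep = (wavelengths >= band_range[0]) & (wavelengths <= band_range[1])
        if not keep.any():
            raise ValueError(f"no bands inside {band_range}")
        cube, wavelengths = cube[:, :, keep], wavelengths[keep]
    return SpectralCube(cube, wavelengths)


def write_envi(cube: SpectralCube, header_path, interleave: str = "bil",
               dtype=np.float32) -> None:
    """Write a cube as an ENVI ``.hdr`` + ``.raw`` pair (atomically)."""
    header_path = Path(header_path)
    interleave = interleave.lower()
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError("write_envi supports float32/float64 only")
    values = cube.values.astype(dtype)
    if interleave == "bil":
        flat = values.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = values
    elif interleave == "bsq":
        flat = values.transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {synthetic greenhouse scene}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = { " + wl + " }\n"
    )
    data_path = header_path.with_suffix(".raw")
    for path, writer in ((header_path, lambda p: p.write_text(header)),
                         (data_path, lambda p: flat.tofile(p))):
        tmp = path.with_name(path.name + ".tmp")
        writer(tmp)
        os.replace(tmp, path)
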