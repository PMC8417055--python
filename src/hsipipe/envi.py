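"""Minimal ENVI-style raster I/O (text header + band-sequential binary).

Writes the classic two-file layout: ``name.hdr`` holding ``key = value``
metadata plus a wavelength list, and ``name.img`` holding the raw array
in band-sequential (BSQ) order.  Only the subset of the header grammar
this pipeline emits is parsed back; cubes are stored as little-endian
64-bit floats (ENVI data type 5).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .containers import SpectralCube
from .errors import ConfigurationError

_DTYPE_CODES = {4: np.float32, 5: np.float64}
_CODE_FOR = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_cube(path, cube: SpectralCube) -> None:
    """Write *cube* as ``path.hdr`` + ``path.img`` (BSQ, float64)."""
    path = Path(path)
    rows, cols, bands = cube.shape
    data = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0))  # BSQ
    img = path.with_suffix(".img")
    hdr = path.with_suffix(".hdr")
    data.astype("<f8").tofile(img)
    wl = ", ".join(f"{w:.10g}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR[np.dtype(np.float64)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"units = {cube.units}\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )


def _parse_header(text: str) -> dict:
    meta: dict = {}
    braces = re.findall(r"(\w[\w ]*?)\s*=\s*\{([^}]*)\}", text, re.S)
    for key, val in braces:
        meta[key.strip()] = [v.strip() for v in val.split(",") if v.strip()]
    for line in text.splitlines():
        if "=" in line and "{" not in line:
            key, _, val = line.partition("=")
            meta[key.strip()] = val.strip()
    return meta


def read_cube(path) -> SpectralCube:
    """Read a cube written by :func:`write_cube`."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    img = path.with_suffix(".img")
    meta = _parse_header(hdr.read_text())
    rows = int(meta["lines"])
    cols = int(meta["samples"])
    bands = int(meta["bands"])
    code = int(meta.get("data type", 5))
    if code not in _DTYPE_CODES:
        raise ConfigurationError(f"unsupported ENVI data type {code}")
    if meta.get("interleave", "bsq").lower() != "bsq":
        raise ConfigurationError("only BSQ interleave is supported")
    data = np.fromfile(img, dtype=np.dtype(_DTYPE_CODES[code]).newbyteorder("<"))
    if data.size != rows * cols * bands:
        raise ConfigurationError(f"{img} size does not match header")
    values = np.moveaxis(data.reshape(bands, rows, cols), 0, 2)
    wl = np.array([float(w) for w in meta["wavelength"]])
    return SpectralCube(values.astype(float), wl, units=str(meta.get("units", "dn")))
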