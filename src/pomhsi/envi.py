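"""Minimal ENVI reader/writer for hyperspectral cubes and mask images.

ENVI stores a cube as a flat binary file plus an ASCII ``.hdr`` sidecar
describing dimensions, data type, interleave and the wavelength list.  This
module supports the subset the pipeline needs: BSQ/BIL/BIP interleaves,
little-endian uint8/uint16/float32/float64 samples, and the ``wavelength``
header list.  Cubes are materialized as :class:`~pomhsi.core.HyperCube`
blocks of shape (lines, samples, bands).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import ConfigurationError, HyperCube, ShapeError

__all__ = ["read_envi", "write_envi", "write_mask", "read_mask"]

# ENVI data type codes <-> numpy dtypes (little-endian)
_DTYPE_TO_CODE = {"uint8": 1, "int16": 2, "int32": 3, "float32": 4, "float64": 5, "uint16": 12}
_CODE_TO_DTYPE = {
    1: np.uint8,
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
}


def _header_path(binary_path: Path) -> Path:
    return binary_path.with_suffix(binary_path.suffix + ".hdr")


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ConfigurationError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        consumed = eq + 1 + (len(body[eq + 1 :]) - len(rest))
        if rest.startswith("{"):
            close = rest.find("}")
            if close == -1:
                raise ConfigurationError(f"unterminated {{...}} block for header key {key!r}")
            fields[key] = rest[1:close].strip()
            i = consumed + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            fields[key] = rest[:nl].strip()
            i = consumed + nl + 1
    return fields


def read_envi(
    header_path: str | Path,
    *,
    assume_grid: tuple[float, float] | None = None,
    kind: str | None = None,
) -> HyperCube:
    """Read an ENVI cube given its ``.hdr`` path (or the binary path).

    ``assume_grid`` supplies ``(lambda_min, lambda_max)`` for headers that
    lack a wavelength list; without it such headers are rejected.  ``kind``
    overrides the cube kind (inferred as "counts" for integer data and
    "reflectance" for floats).
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = _header_path(header_path)
    binary_path = header_path.with_suffix("")
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    if not binary_path.exists():
        raise FileNotFoundError(f"ENVI binary missing for header: {binary_path}")

    fields = _parse_header(header_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ConfigurationError(f"ENVI header missing required field: {exc}") from exc
    if interleave not in ("bsq", "bil", "bip"):
        raise ConfigurationError(f"unsupported interleave {interleave!r}")
    if code not in _CODE_TO_DTYPE:
        raise ConfigurationError(f"unsupported ENVI data type code {code}")
    if int(fields.get("byte order", "0")) != 0:
        raise ConfigurationError("only little-endian (byte order = 0) files are supported")
    dtype = np.dtype(_CODE_TO_DTYPE[code])

    expected = lines * samples * bands * dtype.itemsize
    actual = binary_path.stat().st_size
    if expected != actual:
        raise ShapeError(
            f"ENVI binary size mismatch for {binary_path.name}: "
            f"expected {expected} bytes, found {actual}"
        )
    flat = np.fromfile(binary_path, dtype=dtype)
    if interleave == "bsq":
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = flat.reshape(lines, samples, bands)

    if "wavelength" in fields:
        wavelengths = np.array(
            [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
        )
        if len(wavelengths) != bands:
            raise ShapeError("wavelength list length does not match the band count")
    elif assume_grid is not None:
        wavelengths = np.linspace(assume_grid[0], assume_grid[1], bands)
    else:
        raise ConfigurationError(
            "header has no wavelength list; pass assume_grid=(lambda_min, lambda_max)"
        )

    if kind is None:
        kind = "counts" if np.issubdtype(dtype, np.integer) else "reflectance"
    meta = {"source": str(binary_path), "interleave": interleave}
    if "description" in fields:
        meta["description"] = fields["description"]
    return HyperCube(np.ascontiguousarray(cube), wavelengths, kind, meta)


def write_envi(
    binary_path: str | Path,
    cube: HyperCube,
    *,
    interleave: str = "bsq",
    description: str | None = None,
) -> Path:
    """Write a cube as ENVI binary + ASCII header; returns the header path.

    uint16 counts and float32 reflectance round-trip bit-exactly; other
    dtypes are written as-is when supported.
    """
    binary_path = Path(binary_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ConfigurationError(f"unsupported interleave {interleave!r}")
    values = cube.values
    dtype_name = values.dtype.name
    if dtype_name not in _DTYPE_TO_CODE:
        raise ConfigurationError(f"unsupported dtype {dtype_name} for ENVI output")
    lines, samples, bands = values.shape

    if interleave == "bsq":
        ordered = values.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = values.transpose(0, 2, 1)
    else:
        ordered = values
    binary_path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(ordered, dtype=values.dtype.newbyteorder("<")).tofile(binary_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header_lines = ["ENVI"]
    if description:
        header_lines.append(f"description = {{{description}}}")
    header_lines += [
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_CODE[dtype_name]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
        "",
    ]
    header_path = _header_path(binary_path)
    header_path.write_text("\n".join(header_lines))
    return header_path


def write_mask(binary_path: str | Path, mask: np.ndarray, wavelength_nm: float = 0.0) -> Path:
    """Write a binary mask as a single-band uint8 ENVI image."""
    mask = np.asarray(mask, dtype=bool)
    cube = HyperCube(
        mask.astype(np.uint8)[:, :, None],
        np.array([wavelength_nm if wavelength_nm > 0 else 1.0]),
        "counts",
        {"role": "mask"},
    )
    return write_envi(binary_path, cube, description="binary mask")


def read_mask(header_path: str | Path) -> np.ndarray:
    """Read a single-band ENVI image back as a boolean mask."""
    cube = read_envi(header_path, assume_grid=(1.0, 2.0))
    if cube.n_bands != 1:
        raise ShapeError("mask image must have exactly one band")
    return cube.values[:, :, 0] > 0
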