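"""ENVI hyperspectral data-cube I/O, band slicing, and RGB rendering.

A hyperspectral data-cube records radiance (or, after calibration,
reflectance) along two spatial dimensions and one spectral dimension.
On disk the standard container is the ENVI pair: a plain-text ``.hdr``
header declaring the array geometry and band-center wavelengths, plus a
raw binary file in one of three interleaves (band-interleaved-by-line
being the one produced by push-broom imagers such as the Resonon Pika
series).  In memory the cube is always held as a ``(line, sample, band)``
array regardless of the on-disk interleave; conversion happens only at
the I/O boundary.

Pixel coordinates throughout the package are 0-based ``(row=line,
column=sample)``.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HyperCube",
    "BandImage",
    "EnviFormatError",
    "EnviCorruptionError",
    "read_envi",
    "write_envi",
    "slice_band",
    "render_rgb",
]

# ENVI numeric data-type codes -> numpy dtypes.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


class EnviFormatError(ValueError):
    """Raised when an ENVI header is missing or declares inconsistent fields."""


class EnviCorruptionError(IOError):
    """Raised when the binary companion does not match the header geometry."""


@dataclass
class HyperCube:
    """In-memory hyperspectral cube.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Non-negative radiance or reflectance values.
    wavelengths : ndarray, shape (bands,)
        Strictly increasing band-center wavelengths in nm.
    interleave : str
        Preferred on-disk interleave, one of ``bil``, ``bip``, ``bsq``.
    meta : dict
        Free-form header entries (frame rate, exposure, description, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bil"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got {self.data.ndim}-D")
        if self.interleave not in _INTERLEAVES:
            raise ValueError(f"interleave must be one of {_INTERLEAVES}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                "wavelength vector length "
                f"{len(self.wavelengths)} != band count {self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``.

        Ties are broken toward the lower wavelength.  Requests outside the
        wavelength span (plus half a band spacing on either side) raise.
        """
        wl = self.wavelengths
        spacing = np.diff(wl)
        lo = wl[0] - spacing[0] / 2 if len(spacing) else wl[0]
        hi = wl[-1] + spacing[-1] / 2 if len(spacing) else wl[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside cube range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        dist = np.abs(wl - wavelength_nm)
        # argmin returns the first (lower-wavelength) index on exact ties
        return int(np.argmin(dist))


@dataclass
class BandImage:
    """A single spectral slice of a cube: 2-D (line, sample) brightness."""

    values: np.ndarray
    wavelength: float


def _parse_header(text: str) -> dict:
    """Parse ENVI header text into a {key: value} dict (keys lowercased)."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    # Collapse brace-delimited multi-line values onto one line.
    entries: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^=\{\}]+?)\s*=\s*(\{[^\}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        entries[key] = val
    return entries


def _parse_list(value: str) -> np.ndarray:
    inner = value.strip().lstrip("{").rstrip("}")
    parts = [p for p in re.split(r"[,\s]+", inner) if p]
    return np.array([float(p) for p in parts])


def _binary_path(header_path: str) -> str:
    base, ext = os.path.splitext(header_path)
    if ext.lower() == ".hdr":
        candidates = [base, base + ".img", base + ".bil", base + ".dat", base + ".raw"]
    else:
        candidates = [header_path + ".img"]
    for c in candidates:
        if os.path.exists(c):
            return c
    raise EnviCorruptionError(
        f"no binary companion found for header {header_path!r} "
        f"(tried {candidates})"
    )


def read_envi(header_path: str) -> HyperCube:
    """Read an ENVI header + binary pair into a :class:`HyperCube`.

    The binary is reordered to the package-wide ``(line, sample, band)``
    layout.  Negative sensor values are clamped to zero (reflectance and
    radiance are physically non-negative); the clamp count is logged.

    Raises
    ------
    EnviFormatError
        If a required header field is missing or malformed.
    EnviCorruptionError
        If the binary byte count does not match the declared geometry.
    """
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    with open(header_path, "r") as fh:
        hdr = _parse_header(fh.read())

    required = ("samples", "lines", "bands", "interleave", "data type")
    for key in required:
        if key not in hdr:
            raise EnviFormatError(f"header missing required field {key!r}")
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
    except ValueError as exc:
        raise EnviFormatError(f"non-integer geometry field: {exc}") from exc
    interleave = hdr["interleave"].strip().lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    try:
        dtype = _ENVI_DTYPES[int(hdr["data type"])]
    except (KeyError, ValueError):
        raise EnviFormatError(f"unsupported data type {hdr['data type']!r}")
    byte_order = int(hdr.get("byte order", 0))
    offset = int(hdr.get("header offset", 0))

    if "wavelength" not in hdr:
        raise EnviFormatError("header missing required field 'wavelength'")
    wavelengths = _parse_list(hdr["wavelength"])
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"wavelength list length {len(wavelengths)} != bands {bands}"
        )
    units = hdr.get("wavelength units", "nanometers").strip().lower()
    if units.startswith(("micro", "um")) or units == "micrometers":
        wavelengths = wavelengths * 1000.0

    binary_path = _binary_path(header_path)
    itemsize = np.dtype(dtype).itemsize
    expected = lines * samples * bands * itemsize + offset
    actual = os.path.getsize(binary_path)
    if actual != expected:
        raise EnviCorruptionError(
            f"binary {binary_path!r} is {actual} bytes; header geometry "
            f"({lines}x{samples}x{bands} {np.dtype(dtype).name}, offset "
            f"{offset}) requires {expected}"
        )

    raw = np.fromfile(binary_path, dtype=dtype, offset=offset)
    if byte_order == 1:
        raw = raw.byteswap()
    if interleave == "bil":  # (line, band, sample)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (line, sample, band)
        data = raw.reshape(lines, samples, bands)
    else:  # bsq: (band, line, sample)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    data = np.ascontiguousarray(data).astype(np.result_type(dtype, np.float32))
    n_neg = int(np.count_nonzero(data < 0))
    if n_neg:
        logger.warning("clamped %d negative sensor values to 0", n_neg)
        data = np.clip(data, 0, None)

    meta = {k: v for k, v in hdr.items()
            if k not in required + ("wavelength", "byte order", "header offset")}
    meta["source dtype"] = np.dtype(dtype).name
    return HyperCube(data=data, wavelengths=wavelengths, interleave=interleave,
                     meta=meta)


def write_envi(cube: HyperCube, header_path: str, dtype=np.float32) -> str:
    """Write a cube as an ENVI header + binary pair; returns the binary path.

    The writer defaults to float32 and round-trips losslessly with
    :func:`read_envi` for any of the three interleaves.
    """
    cube.validate()
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI dtype {dtype}")
    base, ext = os.path.splitext(header_path)
    binary_path = base if ext.lower() == ".hdr" else header_path + ".img"
    if ext.lower() != ".hdr":
        header_path = header_path + ".hdr"

    data = np.asarray(cube.data, dtype=dtype)
    if cube.interleave == "bil":
        out = data.transpose(0, 2, 1)  # (line, band, sample)
    elif cube.interleave == "bip":
        out = data
    else:
        out = data.transpose(2, 0, 1)  # (band, line, sample)
    out = np.ascontiguousarray(out)
    out.tofile(binary_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {cube.interleave}",
        "byte order = 0",
        "wavelength units = nanometers",
    ]
    for key, val in cube.meta.items():
        if key == "source dtype":
            continue
        lines.append(f"{key} = {val}")
    lines.append("wavelength = { " + wl + " }")
    with open(header_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return binary_path


def slice_band(cube: HyperCube, wavelength_nm: float) -> BandImage:
    """Extract the band slice whose center wavelength is nearest the request.

    An image of the brightness of the whole scene at (approximately) one
    wavelength.  Ties between two equidistant band centers resolve to the
    lower wavelength.
    """
    idx = cube.band_index(wavelength_nm)
    return BandImage(values=cube.data[:, :, idx].copy(),
                     wavelength=float(cube.wavelengths[idx]))


def render_rgb(
    cube: HyperCube,
    wavelengths_nm: tuple = (600.0, 550.0, 425.0),
    brighten: float = 1.0,
    percentile: float = 99.0,
) -> np.ndarray:
    """Render a 3-channel composite from three band slices (R, G, B order).

    The default triple (600, 550, 425 nm) approximates a natural-color
    image.  Channels are jointly rescaled to [0, 1] by the given upper
    percentile, multiplied by ``brighten``, and clipped at 1 (figure-style
    "brightened by 300%" corresponds to ``brighten=3``).
    """
    if len(wavelengths_nm) != 3:
        raise ValueError("render_rgb requires exactly three wavelengths")
    chans = [slice_band(cube, w).values for w in wavelengths_nm]
    img = np.stack(chans, axis=-1).astype(float)
    scale = np.percentile(img, percentile)
    if scale > 0:
        img = img / scale
    img = np.clip(img * brighten, 0.0, 1.0)
    return img
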