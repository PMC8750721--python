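"""ENVI-style hypercube container and IO.

A hypercube is an ``(rows, cols, bands)`` array with a wavelength axis in
nanometres.  On disk it is the de-facto ENVI pairing of a plain-text header
(``*.hdr``) with a raw binary data file (``*.raw``).  Supported dialects:
interleaves ``bil``/``bip``/``bsq`` and data types uint16 / float32; data are
promoted to float64 in memory.

Coordinate convention used throughout the package: ``(row, col)`` 0-based,
row 0 at the top, band axis last.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError, FormatError, OutOfRangeError, SizeMismatchError

# ENVI numeric data-type codes
_DTYPE_CODES = {4: np.float32, 12: np.uint16}
_DTYPE_NAMES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}
_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass
class Hypercube:
    """In-memory hyperspectral image.

    Parameters
    ----------
    data:
        ``(rows, cols, bands)`` float array of raw intensities or reflectances.
    wavelengths:
        Band-centre wavelengths in nm, strictly increasing, length = bands.
    name:
        Free-text identifier (defaults to the file stem on read).
    meta:
        String key/value map (cultivar, orientation, label, interleave, dtype…).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise FormatError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise AlignmentError(
                f"wavelength axis length {len(self.wavelengths)} != band axis "
                f"extent {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_image(self, target_nm: float) -> np.ndarray:
        """2-D image at the band nearest to ``target_nm``."""
        return self.data[:, :, band_index(self, target_nm)]


@dataclass
class ReferencePair:
    """White and dark reference cubes for reflectance calibration."""

    white: Hypercube
    dark: Hypercube

    def __post_init__(self):
        if self.white.data.shape != self.dark.data.shape:
            raise AlignmentError(
                f"white shape {self.white.data.shape} != dark shape "
                f"{self.dark.data.shape}"
            )
        if not np.allclose(self.white.wavelengths, self.dark.wavelengths):
            raise AlignmentError("white and dark wavelength axes differ")


def band_index(cube: Hypercube, target_nm: float) -> int:
    """Index of the band whose centre is nearest to ``target_nm``.

    Ties break toward the lower index.  Targets outside the wavelength range
    by more than half the median band spacing raise :class:`OutOfRangeError`.
    """
    wl = cube.wavelengths
    half_step = 0.5 * float(np.median(np.diff(wl))) if len(wl) > 1 else 0.0
    if target_nm < wl[0] - half_step or target_nm > wl[-1] + half_step:
        raise OutOfRangeError(
            f"target {target_nm} nm outside [{wl[0]}, {wl[-1]}] nm (±{half_step})"
        )
    # argmin returns the first (lowest) index on ties
    return int(np.argmin(np.abs(wl - target_nm)))


# ---------------------------------------------------------------------------
# Header parsing / writing
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic in header")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # join {...} blocks that may span lines, then split on key = value
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", body, re.M | re.S):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip() if val.endswith("}") else val[1:].strip()
        fields[key] = val
    return fields


def _require(fields: dict, key: str):
    if key not in fields:
        raise FormatError(f"header missing required field '{key}'")
    return fields[key]


def read_envi(header_path) -> Hypercube:
    """Read an ENVI header + raw binary pair into a :class:`Hypercube`.

    ``header_path`` points at the ``.hdr`` file; the data file is the sibling
    named in the header (``data file`` key) or the header path with a ``.raw``
    (fallback ``.dat``) suffix.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file not found: {header_path}")
    fields = _parse_header(header_path.read_text())

    lines = int(_require(fields, "lines"))
    samples = int(_require(fields, "samples"))
    bands = int(_require(fields, "bands"))
    interleave = _require(fields, "interleave").lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave '{interleave}'")
    code = int(_require(fields, "data type"))
    if code not in _DTYPE_CODES:
        raise FormatError(f"unsupported data type code {code}")
    dtype = np.dtype(_DTYPE_CODES[code])
    wl_raw = _require(fields, "wavelength")
    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[,\s]+", wl_raw) if tok], dtype=np.float64
    )
    if len(wavelengths) != bands:
        raise FormatError(
            f"header declares {bands} bands but {len(wavelengths)} wavelengths"
        )

    if "data file" in fields:
        data_path = header_path.parent / fields["data file"]
    else:
        data_path = header_path.with_suffix(".raw")
        if not data_path.exists():
            data_path = header_path.with_suffix(".dat")
    if not data_path.exists():
        raise FormatError(f"data file not found for header {header_path}")

    expected = lines * samples * bands * dtype.itemsize
    actual = data_path.stat().st_size
    if actual != expected:
        raise SizeMismatchError(
            f"{data_path}: {actual} bytes on disk, header implies {expected}"
        )

    flat = np.fromfile(data_path, dtype=dtype)
    if interleave == "bsq":
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = flat.reshape(lines, samples, bands)

    meta = {
        k: v
        for k, v in fields.items()
        if k
        not in {
            "lines", "samples", "bands", "interleave", "data type",
            "wavelength", "wavelength units", "header offset", "byte order",
            "file type", "data file", "description",
        }
    }
    meta["interleave"] = interleave
    meta["dtype"] = dtype.name
    return Hypercube(cube, wavelengths, name=header_path.stem, meta=meta)


def write_envi(cube: Hypercube, header_path, interleave: str | None = None,
               dtype=None) -> None:
    """Write ``cube`` as an ENVI header + raw pair readable by :func:`read_envi`.

    Interleave / dtype default to the cube's ``meta`` entries, falling back to
    ``bil`` / float32.  Writing is lossless for the stored dtype.
    """
    header_path = Path(header_path)
    interleave = (interleave or cube.meta.get("interleave", "bil")).lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(dtype or cube.meta.get("dtype", "float32"))
    if dtype not in _DTYPE_NAMES:
        raise FormatError(f"unsupported dtype {dtype}")

    rows, cols, bands = cube.data.shape
    arr = cube.data.astype(dtype)
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    else:
        flat = arr
    data_path = header_path.with_suffix(".raw")
    flat.tofile(data_path)

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    extra = "".join(
        f"{k} = {v}\n"
        for k, v in cube.meta.items()
        if k not in {"interleave", "dtype"}
    )
    header_path.write_text(
        "ENVI\n"
        f"description = {{{cube.name}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_NAMES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data file = {data_path.name}\n"
        "wavelength units = Nanometers\n"
        f"{extra}"
        f"wavelength = {{{wl}}}\n"
    )
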