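"""Reflectance calibration against white/dark references.

Raw sensor counts are converted to relative reflectance with the standard
two-point correction

    R = (R0 - Rd) / (Rw - Rd)

where R0 is the raw cube, Rd the dark-current image and Rw the white-panel
image.  References may be full frames or, following push-broom practice,
collapsed to a per-(column, band) line average that is broadcast along rows.
"""

from __future__ import annotations

import numpy as np

from .errors import AlignmentError, ParameterError
from .hypercube import Hypercube, ReferencePair


def collapse_reference(ref: Hypercube) -> Hypercube:
    """Average a reference cube over rows to a 1×W×B line reference."""
    return Hypercube(
        ref.data.mean(axis=0, keepdims=True),
        ref.wavelengths,
        name=ref.name + "_line",
        meta=dict(ref.meta),
    )


def _ref_array(ref: Hypercube, raw: Hypercube, which: str) -> np.ndarray:
    if not np.allclose(ref.wavelengths, raw.wavelengths):
        raise AlignmentError(f"{which} reference wavelength axis differs from raw")
    if ref.data.shape == raw.data.shape:
        return ref.data
    if ref.data.shape[1:] == raw.data.shape[1:]:
        # line reference: per-(col, band) average broadcast along rows
        return ref.data.mean(axis=0, keepdims=True)
    raise AlignmentError(
        f"{which} reference shape {ref.data.shape} incompatible with raw "
        f"shape {raw.data.shape}"
    )


def calibrate(raw: Hypercube, refs: ReferencePair, epsilon: float = 1e-6,
              clip: bool = False) -> Hypercube:
    """Convert a raw cube to relative reflectance.

    Denominator entries with ``|Rw - Rd| < epsilon`` yield 0 and are counted
    in the output's ``meta['n_flagged']``.  Negative reflectance (raw below
    dark) is preserved unless ``clip`` is set; the count of negative output
    pixels is always recorded in ``meta['n_negative']``.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    white = _ref_array(refs.white, raw, "white")
    dark = _ref_array(refs.dark, raw, "dark")

    denom = white - dark
    bad = np.abs(denom) < epsilon
    safe = np.where(bad, 1.0, denom)
    out = (raw.data - dark) / safe
    out = np.where(np.broadcast_to(bad, out.shape), 0.0, out)
    n_negative = int(np.sum(out < 0))
    if clip:
        out = np.clip(out, 0.0, None)

    meta = dict(raw.meta)
    meta["calibrated"] = "true"
    meta["n_flagged"] = str(int(np.sum(bad)))
    meta["n_negative"] = str(n_negative)
    meta["dtype"] = "float32"
    return Hypercube(out, raw.wavelengths.copy(), name=raw.name + "_refl", meta=meta)
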