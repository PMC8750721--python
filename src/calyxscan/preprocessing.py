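"""Spectral preprocessing chain for pixel-spectra tables.

Fixed order: wavelength trimming → maximum normalization → Savitzky–Golay
smoothing → mean centering.  Trimming drops noisy detector-edge bands;
max-normalization (divide each spectrum by its own maximum) removes
path-length/scatter gain; the SG filter (second-order polynomial, window 31
by default) smooths along the band axis with polynomial-fit edge handling;
centering subtracts the *training* column mean, which is stored and reapplied
to validation data to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import AlignmentError, DegenerateSpectrumError, ParameterError
from .table import PixelSpectraTable


@dataclass
class PreprocessConfig:
    trim_low_nm: float = 950.0
    trim_high_nm: float = 1650.0
    sg_window: int = 31
    sg_order: int = 2
    normalize: str = "max"      # {max, none}
    center: str = "train-mean"  # {train-mean, none}

    def __post_init__(self):
        if self.sg_window % 2 == 0:
            raise ParameterError("sg_window must be odd")
        if self.sg_order >= self.sg_window:
            raise ParameterError("sg_order must be < sg_window")
        if self.trim_low_nm >= self.trim_high_nm:
            raise ParameterError("trim_low_nm must be < trim_high_nm")
        if self.normalize not in ("max", "none"):
            raise ParameterError(f"unknown normalize tag '{self.normalize}'")
        if self.center not in ("train-mean", "none"):
            raise ParameterError(f"unknown center tag '{self.center}'")


def trim(table: PixelSpectraTable, low_nm: float, high_nm: float) -> PixelSpectraTable:
    """Keep bands with ``low_nm <= λ <= high_nm``."""
    keep = (table.wavelengths >= low_nm) & (table.wavelengths <= high_nm)
    if not keep.any():
        raise ParameterError(
            f"trim window [{low_nm}, {high_nm}] nm keeps no bands of "
            f"[{table.wavelengths[0]}, {table.wavelengths[-1]}] nm"
        )
    return table.replace(table.spectra[:, keep], table.wavelengths[keep])


def max_normalize(table: PixelSpectraTable) -> PixelSpectraTable:
    """Divide each spectrum by its own maximum so every row peaks at 1."""
    row_max = table.spectra.max(axis=1)
    bad = np.flatnonzero(row_max <= 0)
    if len(bad):
        raise DegenerateSpectrumError(bad.tolist())
    return table.replace(table.spectra / row_max[:, None])


def savgol(table: PixelSpectraTable, window: int = 31, order: int = 2) -> PixelSpectraTable:
    """Savitzky–Golay smoothing along the band axis.

    Edges are handled by evaluating the local least-squares polynomial fitted
    to the last full window ('interp' mode), so no bands are discarded.
    """
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if order >= window:
        raise ParameterError("order must be < window")
    if window > table.n_bands:
        raise ParameterError(
            f"window {window} exceeds band count {table.n_bands}"
        )
    if window == 1:
        return table.replace()
    return table.replace(
        savgol_filter(table.spectra, window, order, axis=1, mode="interp")
    )


def mean_center(table: PixelSpectraTable, reference_mean="fit"):
    """Subtract the column mean.

    ``reference_mean='fit'`` computes the mean from this table (training) and
    returns it for reuse; a vector applies a previously fitted mean
    (validation).  Returns ``(centered_table, mean_used)``.
    """
    if isinstance(reference_mean, str):
        if reference_mean != "fit":
            raise ParameterError(f"unknown reference_mean '{reference_mean}'")
        mean = table.spectra.mean(axis=0)
    else:
        mean = np.asarray(reference_mean, dtype=np.float64)
        if mean.shape != (table.n_bands,):
            raise AlignmentError(
                f"reference mean length {mean.shape} != band count {table.n_bands}"
            )
    return table.replace(table.spectra - mean), mean


@dataclass
class FittedPreprocessor:
    """Resolved preprocessing state after fitting on training data."""

    config: PreprocessConfig
    train_mean: np.ndarray = field(default=None)

    def apply(self, table: PixelSpectraTable) -> PixelSpectraTable:
        out = trim(table, self.config.trim_low_nm, self.config.trim_high_nm)
        if self.config.normalize == "max":
            out = max_normalize(out)
        if self.config.sg_window > 1:
            out = savgol(out, self.config.sg_window, self.config.sg_order)
        if self.config.center == "train-mean":
            if self.train_mean is None:
                raise ParameterError("preprocessor not fitted: no training mean")
            out, _ = mean_center(out, self.train_mean)
        return out


def fit_preprocessor(train: PixelSpectraTable,
                     config: PreprocessConfig) -> tuple:
    """Fit the chain on training data; returns (FittedPreprocessor, train_out)."""
    out = trim(train, config.trim_low_nm, config.trim_high_nm)
    if config.normalize == "max":
        out = max_normalize(out)
    if config.sg_window > 1:
        out = savgol(out, config.sg_window, config.sg_order)
    mean = None
    if config.center == "train-mean":
        out, mean = mean_center(out, "fit")
    return FittedPreprocessor(config, mean), out
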