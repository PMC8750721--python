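"""Pixel-spectra tables: the tabular dataset the classifiers consume.

Rows are pixels (observations), columns are spectral bands (features); each
row carries a class label and provenance (sample id, cultivar, orientation,
pixel coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

LABELS = ("healthy", "infested")
PROVENANCE_COLUMNS = ("sample_id", "cultivar", "orientation", "row", "col")


@dataclass
class PixelSpectraTable:
    """N pixel spectra × B bands with labels and provenance."""

    spectra: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                {c: [""] * len(self.labels) for c in PROVENANCE_COLUMNS}
            )
        self.validate()

    def validate(self) -> None:
        n, b = self.spectra.shape
        if len(self.wavelengths) != b:
            raise AlignmentError(
                f"{b} spectral columns but {len(self.wavelengths)} wavelengths"
            )
        if len(self.labels) != n or len(self.provenance) != n:
            raise AlignmentError("labels/provenance length does not match rows")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise FormatError(f"unknown class labels {sorted(bad)}")
        if not np.all(np.isfinite(self.spectra)):
            raise FormatError("table contains non-finite spectra")

    @property
    def n(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def replace(self, spectra=None, wavelengths=None) -> "PixelSpectraTable":
        """Copy with new spectra (and optionally wavelengths), same metadata."""
        return PixelSpectraTable(
            self.spectra.copy() if spectra is None else spectra,
            self.wavelengths.copy() if wavelengths is None else wavelengths,
            self.labels.copy(),
            self.provenance.reset_index(drop=True).copy(),
        )

    def subset_rows(self, idx) -> "PixelSpectraTable":
        idx = np.asarray(idx)
        return PixelSpectraTable(
            self.spectra[idx],
            self.wavelengths.copy(),
            self.labels[idx],
            self.provenance.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat frame: one column per wavelength, then label + provenance."""
        df = pd.DataFrame(self.spectra, columns=[f"{w:.4f}" for w in self.wavelengths])
        df["label"] = self.labels
        for c in PROVENANCE_COLUMNS:
            df[c] = self.provenance[c].values
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PixelSpectraTable":
        df = pd.read_csv(Path(path))
        band_cols = [c for c in df.columns if c not in ("label",) + PROVENANCE_COLUMNS]
        return cls(
            df[band_cols].to_numpy(dtype=np.float64),
            np.array([float(c) for c in band_cols]),
            df["label"].to_numpy(dtype=object),
            df[list(PROVENANCE_COLUMNS)].reset_index(drop=True),
        )
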