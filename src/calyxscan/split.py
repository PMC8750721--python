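"""Dataset assembly and Kennard–Stone train/validation splitting.

Kennard–Stone picks a space-filling training set deterministically: seed with
the two most distant points, then repeatedly add the point whose minimum
Euclidean distance to the already-selected set is largest.  Chemometrics
practice for splitting spectra where a random split could leave whole regions
of spectral space untrained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateGeometryError, ParameterError
from .table import PixelSpectraTable

_CHUNK = 256  # rows per block when scanning pairwise distances


@dataclass
class SplitResult:
    """Disjoint train/validation row indices; train kept in selection order."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    fraction: float

    def to_csv(self, path) -> None:
        n = len(self.train_idx) + len(self.val_idx)
        part = np.empty(n, dtype=object)
        part[self.train_idx] = "train"
        part[self.val_idx] = "validation"
        pd.DataFrame({"index": np.arange(n), "partition": part}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, fraction: float = None) -> "SplitResult":
        df = pd.read_csv(path)
        train = df.loc[df["partition"] == "train", "index"].to_numpy()
        val = df.loc[df["partition"] == "validation", "index"].to_numpy()
        frac = fraction if fraction is not None else len(train) / len(df)
        return cls(train, val, frac)


def _seed_pair(x: np.ndarray) -> tuple:
    """Indices (i, j), i<j, of the most distant pair; ties → lexicographic min."""
    n = len(x)
    sq = np.einsum("ij,ij->i", x, x)
    best, best_pair = -1.0, (0, 1)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (x[start:stop] @ x.T)
        # only consider j > i to get lexicographically minimal tie-breaks
        ii = np.arange(start, stop)[:, None]
        d2[ii >= np.arange(n)[None, :]] = -np.inf
        k = int(np.argmax(d2))  # first occurrence = row-major minimal pair
        i, j = divmod(k, n)
        if d2[i, j] > best:
            best = float(d2[i, j])
            best_pair = (start + i, j)
    if best <= 0.0:
        raise DegenerateGeometryError("all rows identical: no distance structure")
    return best_pair


def kennard_stone(spectra: np.ndarray, train_fraction: float = 0.7) -> SplitResult:
    """Classical Kennard–Stone selection of ``round(fraction·N)`` training rows.

    Deterministic; distance ties are broken toward the lower row index.
    """
    x = np.asarray(spectra, dtype=np.float64)
    if x.ndim != 2 or len(x) < 2:
        raise ParameterError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ParameterError("non-finite values in spectra")
    if not 0.0 < train_fraction <= 1.0:
        raise ParameterError(f"train_fraction must be in (0, 1], got {train_fraction}")
    n = len(x)
    n_train = int(round(train_fraction * n))
    if n_train < 2:
        raise ParameterError(
            f"train quota {n_train} < 2: Kennard–Stone needs at least the seed pair"
        )

    i0, j0 = _seed_pair(x)
    selected = [i0, j0]
    # min squared distance from every point to the selected set
    min_d2 = np.minimum(
        np.einsum("ij,ij->i", x - x[i0], x - x[i0]),
        np.einsum("ij,ij->i", x - x[j0], x - x[j0]),
    )
    min_d2[[i0, j0]] = -np.inf
    while len(selected) < n_train:
        nxt = int(np.argmax(min_d2))  # first occurrence → lower-index tie-break
        selected.append(nxt)
        d2 = np.einsum("ij,ij->i", x - x[nxt], x - x[nxt])
        np.minimum(min_d2, d2, out=min_d2)
        min_d2[nxt] = -np.inf

    train = np.array(selected, dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[train] = False
    return SplitResult(train, np.flatnonzero(mask), train_fraction)


def assemble_dataset(tables: list) -> PixelSpectraTable:
    """Row-wise concatenation of pixel tables sharing an identical wavelength axis."""
    if not tables:
        raise ParameterError("empty table list: nothing to assemble")
    wl = tables[0].wavelengths
    for t in tables[1:]:
        if not np.array_equal(t.wavelengths, wl):
            raise AlignmentError("tables have differing wavelength axes")
    return PixelSpectraTable(
        np.vstack([t.spectra for t in tables]),
        wl.copy(),
        np.concatenate([t.labels for t in tables]),
        pd.concat([t.provenance for t in tables], ignore_index=True),
    )
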