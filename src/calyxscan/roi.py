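"""Automatic calyx-centred region-of-interest acquisition.

Codling-moth larvae mostly enter the fruit at the calyx (blossom) end, so the
pixel dataset is built from a circular ROI centred on the calyx.  The chain:

1. threshold the image at a single segmentation band (default 1084 nm) to
   isolate the bright fruit flesh; filling the holes of that mask yields the
   fruit disk, and the sub-threshold pixels *inside* the disk are the dark
   calyx-cavity candidate;
2. erode the calyx candidate with a disk structuring element to a solid blob;
3. take the centroid of the largest 8-connected surviving component;
4. draw a circular mask (default 50 px diameter, inclusive boundary) around
   that centroid.

Masks are plain boolean ``(H, W)`` numpy arrays.  Out-of-bounds pixels count
as background for erosion (an all-true mask shrinks at the borders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import EmptyMaskError, NoCalyxError, ParameterError, SegmentationError
from .hypercube import Hypercube, band_index
from .table import PROVENANCE_COLUMNS, PixelSpectraTable

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass
class RoiResult:
    """Final circular ROI plus the geometry that produced it."""

    mask: np.ndarray
    centroid: tuple
    diameter_px: int
    seg_wavelength_nm: float
    n_pixels: int
    params: dict = field(default_factory=dict)


def _otsu(values: np.ndarray) -> float:
    if np.ptp(values) == 0:
        raise SegmentationError("constant intensities: no threshold exists")
    return float(threshold_otsu(values, nbins=256))


def segment_scene(cube: Hypercube, seg_nm: float, method: str = "otsu",
                  threshold: float | None = None) -> np.ndarray:
    """Fruit-flesh mask at the segmentation band.

    True where the pixel is bright fruit flesh; the dark background *and* the
    dark calyx cavity both fall below the threshold.  ``method='otsu'`` picks
    the between-class-variance threshold on the band histogram (256 bins);
    ``method='fixed'`` uses the supplied ``threshold``.  Raises
    :class:`SegmentationError` when no foreground survives.
    """
    img = cube.band_image(seg_nm)
    if method == "fixed":
        if threshold is None:
            raise ParameterError("method='fixed' requires a threshold")
        flesh = img > threshold
    elif method == "otsu":
        flesh = img > _otsu(img.ravel())
    else:
        raise ParameterError(f"unknown threshold method '{method}'")
    if not flesh.any():
        raise SegmentationError("empty foreground after thresholding")
    return flesh


def erode(mask: np.ndarray, selem_radius: int) -> np.ndarray:
    """Binary erosion with a disk structuring element; radius 0 is identity."""
    if selem_radius < 0:
        raise ParameterError("selem_radius must be non-negative")
    if selem_radius == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=disk(selem_radius),
                                  border_value=0)


def calyx_centroid(mask: np.ndarray) -> tuple:
    """Centroid (row, col) of the largest 8-connected component of ``mask``."""
    if not mask.any():
        raise NoCalyxError("empty mask: no calyx component")
    labelled, n = ndimage.label(mask, structure=_EIGHT)
    sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
    rows, cols = np.nonzero(labelled == (int(np.argmax(sizes)) + 1))
    return (float(rows.mean()), float(cols.mean()))


def circular_roi(center: tuple, diameter_px: int, shape: tuple) -> np.ndarray:
    """Disk mask: pixel centres within ``diameter_px/2`` of ``center``, inclusive."""
    if diameter_px < 1:
        raise ParameterError(f"diameter_px must be >= 1, got {diameter_px}")
    h, w = shape
    r0, c0 = center
    if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
        raise ParameterError(f"center {center} outside image bounds {shape}")
    rr, cc = np.ogrid[:h, :w]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= (diameter_px / 2.0) ** 2


def rect_roi(center: tuple, height: int = 10, width: int = 10,
             shape: tuple = None) -> np.ndarray:
    """Axis-aligned height×width rectangle centred at ``center``, border-clipped."""
    if height < 1 or width < 1:
        raise ParameterError("rectangle sides must be positive")
    h, w = shape
    r0, c0 = int(round(center[0])), int(round(center[1]))
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ParameterError(f"center {center} outside image bounds {shape}")
    mask = np.zeros((h, w), dtype=bool)
    top = r0 - (height - 1) // 2
    left = c0 - (width - 1) // 2
    mask[max(top, 0):min(top + height, h), max(left, 0):min(left + width, w)] = True
    return mask


def acquire_roi(cube: Hypercube, seg_nm: float = 1084.0, diameter_px: int = 50,
                selem_radius: int = 2, method: str = "otsu",
                threshold: float | None = None,
                min_contrast: float = 0.2) -> RoiResult:
    """Full automatic ROI chain: segment → erode → centroid → circle.

    ``min_contrast`` guards against scenes without a calyx: the mean flesh
    intensity must exceed the mean calyx-candidate intensity by at least this
    fraction of the flesh level, otherwise :class:`NoCalyxError` is raised
    (on a uniform fruit disk a threshold always "finds" something, but only
    noise).
    """
    img = cube.band_image(seg_nm)
    flesh = segment_scene(cube, seg_nm, method=method, threshold=threshold)
    # fruit disk = flesh with its interior cavities filled; the calyx is
    # exactly the dark (sub-threshold) region *inside* the disk
    fruit = ndimage.binary_fill_holes(flesh)
    candidate = fruit & ~flesh
    if not candidate.any():
        raise NoCalyxError("no dark region inside the fruit disk")
    contrast = img[flesh].mean() - img[candidate].mean()
    if contrast < min_contrast * abs(img[flesh].mean()):
        raise NoCalyxError(
            f"calyx/flesh contrast {contrast:.4g} below threshold; "
            "scene has no distinct calyx"
        )
    eroded = erode(candidate, selem_radius)
    if not eroded.any():
        raise NoCalyxError("calyx candidate vanished under erosion")
    centroid = calyx_centroid(eroded)
    mask = circular_roi(centroid, diameter_px, img.shape)
    return RoiResult(
        mask=mask,
        centroid=centroid,
        diameter_px=diameter_px,
        seg_wavelength_nm=float(seg_nm),
        n_pixels=int(mask.sum()),
        params={
            "method": method,
            "threshold": threshold,
            "selem_radius": selem_radius,
            "min_contrast": min_contrast,
            "seg_band_index": band_index(cube, seg_nm),
        },
    )


def extract_pixel_spectra(cube: Hypercube, mask: np.ndarray, label: str,
                          sample_id: str = "", cultivar: str = "",
                          orientation: str = "") -> PixelSpectraTable:
    """Unfold the masked pixels into a labelled table, row-major pixel order."""
    if mask.shape != cube.data.shape[:2]:
        raise ParameterError(
            f"mask shape {mask.shape} != cube spatial shape {cube.data.shape[:2]}"
        )
    rows, cols = np.nonzero(mask)  # np.nonzero scans row-major
    if len(rows) == 0:
        raise EmptyMaskError("mask selects no pixels")
    import pandas as pd

    prov = pd.DataFrame({
        "sample_id": sample_id, "cultivar": cultivar,
        "orientation": orientation, "row": rows, "col": cols,
    }, columns=list(PROVENANCE_COLUMNS))
    return PixelSpectraTable(
        cube.data[rows, cols, :],
        cube.wavelengths.copy(),
        np.array([label] * len(rows), dtype=object),
        prov,
    )


def mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over the true pixels of ``mask``."""
    if not mask.any():
        raise EmptyMaskError("mask selects no pixels")
    return cube.data[mask].mean(axis=0)


def mask_to_rle(mask: np.ndarray) -> str:
    """Run-length encode a mask (row-major) as 'H W v0 n0 n1 …' text."""
    flat = mask.ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    runs = np.diff(np.concatenate(([0], changes + 1, [flat.size])))
    return " ".join(
        [str(mask.shape[0]), str(mask.shape[1]), str(int(flat[0]))]
        + [str(int(r)) for r in runs]
    )


def rle_to_mask(text: str) -> np.ndarray:
    toks = text.split()
    h, w, v0 = int(toks[0]), int(toks[1]), int(toks[2])
    runs = np.array([int(t) for t in toks[3:]])
    vals = (np.arange(len(runs)) + v0) % 2 == 1
    return np.repeat(vals, runs).reshape(h, w)


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a mask as an 8-bit 0/255 PNG."""
    from PIL import Image

    Image.fromarray((mask.astype(np.uint8)) * 255).save(path)
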