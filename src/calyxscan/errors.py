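"""Exception hierarchy.

All package-raised errors derive from :class:`CalyxScanError` so callers can
catch pipeline failures with one clause while tests assert precise subclasses.
"""


class CalyxScanError(Exception):
    """Base class for all calyxscan errors."""


class FormatError(CalyxScanError):
    """A file does not conform to the expected on-disk format."""


class SizeMismatchError(FormatError):
    """Binary payload size disagrees with the header declaration."""


class OutOfRangeError(CalyxScanError):
    """A requested wavelength lies outside the cube's spectral range."""


class AlignmentError(CalyxScanError):
    """Two objects that must share an axis (wavelengths, features) do not."""


class ParameterError(CalyxScanError):
    """An argument violates its documented constraints."""


class SegmentationError(CalyxScanError):
    """Thresholding produced no usable foreground."""


class NoCalyxError(SegmentationError):
    """No calyx candidate region survived segmentation + erosion."""


class EmptyMaskError(CalyxScanError):
    """An operation requiring a non-empty pixel mask received an empty one."""


class DegenerateSpectrumError(CalyxScanError):
    """One or more spectra cannot be normalized (non-positive maximum)."""

    def __init__(self, rows):
        self.rows = list(rows)
        super().__init__(f"spectra with non-positive maximum at rows {self.rows}")


class DegenerateGeometryError(CalyxScanError):
    """Point configuration has no usable geometry (e.g. all rows identical)."""


class DegenerateLabelError(CalyxScanError):
    """Classification requested with fewer than two classes present."""
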