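"""Image and ROI data model with readers/writers for grayscale B-mode frames.

A :class:`BModeImage` is an 8-bit grayscale frame plus its physical pixel
spacing in mm; a :class:`CircularROI` is the rasterized disk used for both
echogenicity and texture measurements.  Supported on-disk formats are 8-bit
grayscale TIFF and PNG, and single-frame MONOCHROME2 DICOM carrying a
``PixelSpacing`` tag.  ROI sidecars are small JSON files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Spacing used when a file carries no physical calibration (mm/pixel).
DEFAULT_SPACING_X_MM = 0.017578
DEFAULT_SPACING_Y_MM = 0.0176


class UnsupportedFormatError(ValueError):
    """Raised for multi-frame, color, or otherwise unreadable input."""


class ROIOutOfBoundsError(ValueError):
    """Raised when a bound ROI extends outside the image grid."""

    def __init__(self, clipped):
        self.clipped = list(clipped)
        super().__init__(
            f"ROI extends outside image bounds; {len(self.clipped)} clipped "
            f"pixels, first few: {self.clipped[:5]}"
        )


@dataclass
class BModeImage:
    """2D grayscale B-mode frame with physical pixel spacing.

    ``pixels`` is a (rows, cols) uint8 array, row index increasing downward
    (axial/depth direction), 0-based.  ``meta`` holds free-form acquisition
    metadata (subject id, age, lobe, gain, dynamic range ...).
    """

    pixels: np.ndarray
    pixel_spacing_x_mm: float = DEFAULT_SPACING_X_MM
    pixel_spacing_y_mm: float = DEFAULT_SPACING_Y_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("gray levels must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.pixel_spacing_x_mm <= 0 or self.pixel_spacing_y_mm <= 0:
            raise ValueError("pixel spacings must be strictly positive")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class CircularROI:
    """Rasterized circular region of interest.

    A pixel belongs to the disk iff its center lies within Euclidean distance
    ``r = sqrt(nominal_area_px / pi)`` of the ROI center, so the realized
    pixel count may differ slightly from the nominal area (97-101 pixels for
    the conventional 100-pixel ROI).
    """

    center_x_px: float
    center_y_px: float
    nominal_area_px: int
    pixel_set: tuple = ()

    def __len__(self):
        return len(self.pixel_set)

    def bound_pixels(self, image: BModeImage):
        """Pixel set validated against ``image``; raises if any pixel falls
        outside the grid."""
        h, w = image.shape
        clipped = [(r, c) for r, c in self.pixel_set
                   if not (0 <= r < h and 0 <= c < w)]
        if clipped:
            raise ROIOutOfBoundsError(clipped)
        return self.pixel_set


def make_circular_roi(center_x_px: float, center_y_px: float,
                      nominal_area_px: int = 100) -> CircularROI:
    """Rasterize a disk of ``nominal_area_px`` pixels centered at
    ``(center_x_px, center_y_px)`` (x = column, y = row)."""
    if nominal_area_px < 1:
        raise ValueError("nominal_area_px must be >= 1")
    r = math.sqrt(nominal_area_px / math.pi)
    r2 = r * r
    rows = range(int(math.floor(center_y_px - r)), int(math.ceil(center_y_px + r)) + 1)
    cols = range(int(math.floor(center_x_px - r)), int(math.ceil(center_x_px + r)) + 1)
    pixels = tuple(
        (row, col)
        for row in rows
        for col in cols
        if (row - center_y_px) ** 2 + (col - center_x_px) ** 2 <= r2
    )
    if not pixels:  # pragma: no cover - r >= sqrt(1/pi) always hits center
        pixels = ((int(round(center_y_px)), int(round(center_x_px))),)
    return CircularROI(center_x_px, center_y_px, nominal_area_px, pixels)


def roi_mask(roi: CircularROI, shape) -> np.ndarray:
    """Boolean mask of the ROI on a grid of ``shape``."""
    mask = np.zeros(shape, dtype=bool)
    rows, cols = zip(*roi.pixel_set)
    mask[list(rows), list(cols)] = True
    return mask


def save_roi(roi: CircularROI, path) -> None:
    Path(path).write_text(json.dumps({
        "center_x_px": roi.center_x_px,
        "center_y_px": roi.center_y_px,
        "nominal_area_px": roi.nominal_area_px,
    }))


def load_roi(path) -> CircularROI:
    spec = json.loads(Path(path).read_text())
    return make_circular_roi(spec["center_x_px"], spec["center_y_px"],
                             spec["nominal_area_px"])


def _infer_format(path, fmt=None):
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    return {".tif": "tiff", ".tiff": "tiff", ".png": "png",
            ".dcm": "dicom", ".dicom": "dicom"}.get(suffix, suffix.lstrip("."))


def read_image(path, fmt: str | None = None) -> BModeImage:
    """Read an 8-bit grayscale frame from TIFF, PNG, or single-frame DICOM.

    When the file carries no pixel-spacing calibration the standard
    resampling constants are filled in and flagged via
    ``meta['spacing_assumed']``.
    """
    fmt = _infer_format(path, fmt)
    meta: dict = {"source": str(path), "format": fmt}
    if fmt == "tiff":
        import tifffile

        arr = tifffile.imread(path)
        sx = sy = None
    elif fmt == "png":
        from PIL import Image

        with Image.open(path) as im:
            if im.mode not in ("L", "I;16", "1"):
                raise UnsupportedFormatError(
                    f"PNG mode {im.mode!r} is not single-channel grayscale")
            arr = np.asarray(im.convert("L"))
        sx = sy = None
    elif fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise UnsupportedFormatError("DICOM input is not grayscale "
                                         f"(SamplesPerPixel={ds.SamplesPerPixel})")
        if int(getattr(ds, "NumberOfFrames", 1)) != 1:
            raise UnsupportedFormatError("multi-frame DICOM input "
                                         f"({ds.NumberOfFrames} frames)")
        arr = ds.pixel_array
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            # DICOM PixelSpacing is (row spacing, column spacing) = (y, x)
            sy, sx = float(spacing[0]), float(spacing[1])
        else:
            sx = sy = None
    else:
        raise UnsupportedFormatError(f"unknown image format {fmt!r}")

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        raise UnsupportedFormatError("color (multi-channel) input")
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"expected a single 2D frame, got array of shape {arr.shape}")
    if sx is None:
        sx, sy = DEFAULT_SPACING_X_MM, DEFAULT_SPACING_Y_MM
        meta["spacing_assumed"] = True
    return BModeImage(arr, sx, sy, meta)


def write_image(image: BModeImage, path, fmt: str | None = None) -> None:
    """Write ``image`` as 8-bit grayscale TIFF, PNG, or DICOM."""
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, image.pixels)
    elif fmt == "png":
        from PIL import Image

        Image.fromarray(image.pixels, mode="L").save(path)
    elif fmt == "dicom":
        _write_dicom(image, path)
    else:
        raise UnsupportedFormatError(f"unknown image format {fmt!r}")


def _write_dicom(image: BModeImage, path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{image.pixel_spacing_y_mm:.6f}",
                       f"{image.pixel_spacing_x_mm:.6f}"]
    ds.PixelData = image.pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)
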