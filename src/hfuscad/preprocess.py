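"""ROI signal conditioning ahead of texture extraction.

Fixed three-step chain: Gaussian smoothing of the ROI bounding-box patch
(reflect boundary), winsorization at mean +/- k SD, and relative min-max
discretization into ``n_gray_levels`` integer levels.  The order matters and
is asserted against in tests: discretizing before outlier correction yields
different level grids.

The smoothing scale is given in mm ("kernel: X, Y = 0.018 mm") and is
interpreted as the Gaussian sigma per axis; at the standard pixel spacing it
is almost exactly one pixel.  The alternative FWHM reading would give
sigma ~0.43 px, i.e. a near-identity filter; the sigma reading is used
throughout and documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from hfuscad.images import BModeImage, CircularROI, roi_mask


@dataclass(frozen=True)
class PreprocessParams:
    gaussian_kernel_mm: float = 0.018
    padding: str = "reflect"
    clip_k: float = 3.0
    n_gray_levels: int = 256
    rescaling: str = "relative"
    #: drop (rather than winsorize) pixels outside mean +/- k SD
    exclude_outliers: bool = False

    def __post_init__(self):
        if self.gaussian_kernel_mm < 0:
            raise ValueError("gaussian_kernel_mm must be >= 0")
        if self.clip_k <= 0:
            raise ValueError("clip_k must be > 0")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if self.rescaling != "relative":
            raise ValueError("only relative (min-max) rescaling is supported")


@dataclass
class ROIPatch:
    """Real-valued patch over the ROI bounding box with its disk mask."""

    values: np.ndarray
    mask: np.ndarray
    origin: tuple  # (row, col) of the bounding box in the source image

    def masked(self):
        return self.values[self.mask]


def smooth_roi(image: BModeImage, roi: CircularROI,
               params: PreprocessParams | None = None) -> ROIPatch:
    """Gaussian-smooth the ROI bounding-box patch.

    Sigma per axis is ``gaussian_kernel_mm / pixel_spacing``; filtering runs
    on the rectangular bounding box with reflect padding, and the disk mask
    is applied only afterwards (downstream).
    """
    if params is None:
        params = PreprocessParams()
    pixels = roi.bound_pixels(image)
    rows, cols = zip(*pixels)
    r0, r1 = min(rows), max(rows)
    c0, c1 = min(cols), max(cols)
    patch = image.pixels[r0:r1 + 1, c0:c1 + 1].astype(float)
    mask = roi_mask(roi, image.shape)[r0:r1 + 1, c0:c1 + 1]
    sig_y = params.gaussian_kernel_mm / image.pixel_spacing_y_mm
    sig_x = params.gaussian_kernel_mm / image.pixel_spacing_x_mm
    if 0 < min(sig_x, sig_y) < 0.25:
        warnings.warn("Gaussian kernel below 0.25 px: filter is close to "
                      "identity", stacklevel=2)
    if max(sig_x, sig_y) > 0:
        patch = ndimage.gaussian_filter(patch, (sig_y, sig_x),
                                        mode=params.padding)
    return ROIPatch(patch, mask, (r0, c0))


def clip_outliers(patch: ROIPatch, clip_k: float = 3.0,
                  exclude: bool = False) -> ROIPatch:
    """Winsorize in-mask values at mean +/- ``clip_k`` population SD.

    With ``exclude=True`` outlying pixels are removed from the mask instead
    of being clamped (this changes ROI geometry for GLCM adjacency and is
    off by default).  A constant patch (SD = 0) is returned unchanged.
    """
    vals = patch.masked()
    if vals.size < 2:
        raise ValueError("outlier correction needs >= 2 in-mask pixels")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in ROI patch")
    mu = vals.mean()
    sd = vals.std()  # population SD
    if sd == 0:
        return ROIPatch(patch.values.copy(), patch.mask.copy(), patch.origin)
    lo, hi = mu - clip_k * sd, mu + clip_k * sd
    if exclude:
        keep = (patch.values >= lo) & (patch.values <= hi)
        return ROIPatch(patch.values.copy(), patch.mask & keep, patch.origin)
    return ROIPatch(np.clip(patch.values, lo, hi), patch.mask.copy(),
                    patch.origin)


@dataclass
class LevelGrid:
    """Integer gray-level grid in ``[0, n_gray_levels - 1]`` with mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_gray_levels: int
    degenerate: bool = False


def discretize(patch: ROIPatch, n_gray_levels: int = 256) -> LevelGrid:
    """Relative (min-max) discretization into ``n_gray_levels`` bins.

    ``level = floor((v - vmin) / (vmax - vmin) * n)`` with the top edge
    closed (v = vmax maps to n - 1); vmin/vmax are taken over the in-mask
    pixels.  A constant patch yields all-zero levels flagged degenerate.
    """
    vals = patch.masked()
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return LevelGrid(np.zeros_like(patch.values, dtype=np.intp),
                         patch.mask.copy(), n_gray_levels, degenerate=True)
    lv = np.floor((patch.values - vmin) / (vmax - vmin) * n_gray_levels)
    lv = np.clip(lv, 0, n_gray_levels - 1).astype(np.intp)
    return LevelGrid(lv, patch.mask.copy(), n_gray_levels)


def preprocess_roi(image: BModeImage, roi: CircularROI,
                   params: PreprocessParams | None = None) -> LevelGrid:
    """Full chain: smooth -> clip -> discretize."""
    if params is None:
        params = PreprocessParams()
    patch = smooth_roi(image, roi, params)
    patch = clip_outliers(patch, params.clip_k, params.exclude_outliers)
    return discretize(patch, params.n_gray_levels)
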