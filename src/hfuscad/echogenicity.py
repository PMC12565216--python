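"""Gray-level-histogram statistics and the hepatorenal index (HRI).

The HRI normalizes caudate-lobe liver echogenicity to that of the right
renal cortex: the ratio of mean raw (pre-discretization) gray levels of two
100-pixel circular ROIs placed on the same frame.  As a ratio it cancels a
global gain factor applied to the whole image, which is the point: it
compensates for variability in scanning parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hfuscad.images import BModeImage, CircularROI


@dataclass(frozen=True)
class HRIMeasurement:
    liver_mean: float
    renal_mean: float
    hri: float
    subject: str | None = None
    age_weeks: float | None = None

    def __post_init__(self):
        if self.renal_mean <= 0:
            raise ValueError("renal mean gray level must be > 0")
        if abs(self.hri - self.liver_mean / self.renal_mean) > 1e-12:
            raise ValueError("hri must equal liver_mean / renal_mean")


def roi_mean_intensity(image: BModeImage, roi: CircularROI) -> float:
    """Arithmetic mean of raw gray levels inside the disk."""
    pixels = roi.bound_pixels(image)
    if not pixels:
        raise ValueError("empty ROI")
    rows, cols = zip(*pixels)
    return float(image.pixels[list(rows), list(cols)].mean())


def compute_hri(liver_mean: float, renal_mean: float,
                subject: str | None = None,
                age_weeks: float | None = None) -> HRIMeasurement:
    """Hepatorenal index from the two ROI means."""
    if renal_mean <= 0:
        raise ZeroDivisionError("degenerate denominator: renal mean must be "
                                "> 0")
    return HRIMeasurement(float(liver_mean), float(renal_mean),
                          float(liver_mean) / float(renal_mean),
                          subject, age_weeks)


def hri_from_image(image: BModeImage, liver_roi: CircularROI,
                   renal_roi: CircularROI, **ids) -> HRIMeasurement:
    """HRI with both ROIs on the same frame (the standard, single-view
    acquisition; cross-frame use should go through :func:`compute_hri`
    explicitly)."""
    return compute_hri(roi_mean_intensity(image, liver_roi),
                       roi_mean_intensity(image, renal_roi), **ids)
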