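"""Synthetic B-mode speckle generator with steatosis-grade-dependent tissue.

The scattering model is fully developed speckle: each pixel carries a
zero-mean circular complex Gaussian scattering amplitude whose variance is
the local tissue backscatter ("echogenicity") map.  The complex field is
blurred with an anisotropic Gaussian point-spread function matching the
40 MHz probe resolution (35 um axial, 80 um lateral FWHM), the envelope is
log-compressed over a 60 dB dynamic range referenced to the per-image
envelope maximum, and quantized to 8 bits.

Steatosis grade (0-3, mapped from the histological severity class) controls
four tissue properties of the liver region:

``echogenicity_ratio`` (rho)
    liver backscatter variance relative to the renal cortex (fixed at 1);
    rises with fat content, driving the hepatorenal index upward.
``heterogeneity_tau`` / ``correlation_length_mm``
    a multiplicative lognormal field (log-SD tau, Gaussian correlation of
    FWHM ell) modelling patchy, coarse parenchymal echotexture.
``hypoechoic_fraction``
    area fraction of fine hypoechoic structure (sinusoids, small portal and
    hepatic venules) visible in normal parenchyma; fat infiltration
    progressively obliterates these interfaces ("vascular blurring"), so the
    fraction *decreases* with grade.
``coherence_extra_px``
    extra correlation of the scattered field as sub-resolution lipid
    droplets pack the tissue, implemented as a small additional Gaussian
    smoothing of the complex field over the liver (power-renormalized so
    region brightness is unchanged); grows with grade and smooths the
    speckle grain.

A bright specular band (reflector) at the bottom of the frame stands in for
the strong capsular/diaphragmatic interface that dominates the display
maximum on fixed-gain scanners; its strength sets where parenchyma sits
within the 60 dB window and was calibrated once so that the measured
grade-0 hepatorenal index lands near the no-steatosis class mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from hfuscad.images import BModeImage, make_circular_roi

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # approx 1/2.355

#: Region label codes in :class:`TissueMap.region_labels`.
BACKGROUND, LIVER, RENAL_CORTEX, REFLECTOR = 0, 1, 2, 3

#: Frozen display/scene calibration (relative to renal-cortex variance = 1).
BACKGROUND_VAR = 0.01
REFLECTOR_VAR = 1.4e4
HYPO_DEPTH = 0.05        # variance of hypoechoic structure relative to liver
HYPO_SIGMA_PX = 2.0      # spatial scale of the hypoechoic blob field


class GradeParams(NamedTuple):
    echogenicity_ratio: float
    heterogeneity_tau: float
    correlation_length_mm: float
    hypoechoic_fraction: float
    coherence_extra_px: float


#: Monotone steatosis-grade map, calibrated once and frozen.
GRADE_TABLE: dict[int, GradeParams] = {
    0: GradeParams(0.55, 0.05, 0.05, 0.25, 0.0),
    1: GradeParams(0.85, 0.15, 0.10, 0.18, 0.4),
    2: GradeParams(1.10, 0.25, 0.15, 0.12, 0.8),
    3: GradeParams(1.35, 0.35, 0.20, 0.06, 1.2),
}


class LayoutError(ValueError):
    """Raised when scene regions overlap or are empty."""


class DegenerateInputError(ValueError):
    """Raised for an all-zero tissue map (log of zero envelope)."""


@dataclass(frozen=True)
class SimulationParams:
    """Scanner and tissue parameters for one simulated frame."""

    echogenicity_ratio: float = 1.0
    heterogeneity_tau: float = 0.0
    correlation_length_mm: float = 0.05
    hypoechoic_fraction: float = 0.0
    coherence_extra_px: float = 0.0
    psf_axial_fwhm_mm: float = 0.035
    psf_lateral_fwhm_mm: float = 0.080
    dynamic_range_db: float = 60.0
    pixel_spacing_x_mm: float = 0.017578
    pixel_spacing_y_mm: float = 0.0176
    grade: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.echogenicity_ratio <= 0:
            raise ValueError("echogenicity_ratio must be > 0")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic_range_db must be > 0")
        if self.psf_axial_fwhm_mm <= 0 or self.psf_lateral_fwhm_mm <= 0:
            raise ValueError("PSF FWHMs must be > 0")
        if self.heterogeneity_tau > 0 and self.correlation_length_mm <= 0:
            raise ValueError("correlation length must be > 0 when tau > 0")


def params_for_grade(grade: int, seed: int = 0, **overrides) -> SimulationParams:
    """Simulation parameters for a steatosis grade in {0, 1, 2, 3}."""
    gp = GRADE_TABLE[int(grade)]
    return SimulationParams(
        echogenicity_ratio=gp.echogenicity_ratio,
        heterogeneity_tau=gp.heterogeneity_tau,
        correlation_length_mm=gp.correlation_length_mm,
        hypoechoic_fraction=gp.hypoechoic_fraction,
        coherence_extra_px=gp.coherence_extra_px,
        grade=int(grade),
        seed=seed,
        **overrides,
    )


@dataclass(frozen=True)
class Layout:
    """Scene geometry: rectangular liver, renal-cortex and reflector regions
    (row/col slices on a ``size`` x ``size`` grid) plus standard measurement
    ROI centers ((row, col), 100-pixel disks)."""

    size: int
    liver: tuple          # ((row0, row1), (col0, col1))
    cortex: tuple
    reflector: tuple
    liver_roi_centers: tuple
    cortex_roi_center: tuple

    def region_slices(self, name):
        (r0, r1), (c0, c1) = getattr(self, name)
        return slice(r0, r1), slice(c0, c1)


def default_layout(size: int = 256) -> Layout:
    """Default two-organ scene: liver band above, renal cortex below, bright
    specular band at the bottom."""
    def s(a, b):
        return (round(a * size / 256), round(b * size / 256))

    return Layout(
        size=size,
        liver=(s(20, 120), s(20, 236)),
        cortex=(s(150, 230), s(60, 196)),
        reflector=(s(240, 244), s(40, 216)),
        liver_roi_centers=(
            (round(50 * size / 256), round(80 * size / 256)),
            (round(50 * size / 256), round(176 * size / 256)),
            (round(90 * size / 256), round(80 * size / 256)),
            (round(90 * size / 256), round(176 * size / 256)),
        ),
        cortex_roi_center=(round(190 * size / 256), round(128 * size / 256)),
    )


@dataclass
class TissueMap:
    """Backscatter-variance field with region labels."""

    echogenicity: np.ndarray
    region_labels: np.ndarray
    heterogeneity_tau: float
    correlation_length_mm: float
    layout: Layout

    def __post_init__(self):
        if np.any(self.echogenicity < 0):
            raise ValueError("echogenicity must be non-negative")
        if not np.any(self.region_labels == LIVER):
            raise LayoutError("liver region is empty")
        if not np.any(self.region_labels == RENAL_CORTEX):
            raise LayoutError("renal-cortex region is empty")


def _check_disjoint(layout: Layout):
    grid = np.zeros((layout.size, layout.size), dtype=np.uint8)
    for name in ("liver", "cortex", "reflector"):
        sl = layout.region_slices(name)
        if grid[sl].any():
            raise LayoutError(f"region {name!r} overlaps another region")
        grid[sl] = 1


def make_tissue_map(params: SimulationParams, layout: Layout | None = None,
                    rng: np.random.Generator | None = None) -> TissueMap:
    """Build the backscatter-variance map for one frame.

    The renal cortex is fixed at variance 1; the liver carries
    ``rho x lognormal(tau, ell) x hypoechoic-structure`` variance, with both
    multiplicative fields normalized so the liver *mean* variance equals
    ``rho`` (the lognormal by its analytic mean, the blob field by its
    expected coverage).
    """
    if layout is None:
        layout = default_layout()
    _check_disjoint(layout)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    size = layout.size
    spacing = params.pixel_spacing_y_mm

    v = np.ones((size, size))
    if params.heterogeneity_tau > 0:
        g = rng.standard_normal((size, size))
        sig = params.correlation_length_mm / spacing * _FWHM_TO_SIGMA
        g = ndimage.gaussian_filter(g, sig, mode="wrap")
        g /= g.std()
        tau = params.heterogeneity_tau
        v = np.exp(tau * g - tau**2 / 2.0)
    if params.hypoechoic_fraction > 0:
        frac = params.hypoechoic_fraction
        b = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                    HYPO_SIGMA_PX, mode="wrap")
        blob = (b > np.quantile(b, 1.0 - frac)).astype(float)
        factor = (1.0 - (1.0 - HYPO_DEPTH) * blob)
        factor /= (1.0 - (1.0 - HYPO_DEPTH) * frac)
        v = v * factor

    var = np.full((size, size), BACKGROUND_VAR)
    labels = np.full((size, size), BACKGROUND, dtype=np.uint8)
    liver_sl = layout.region_slices("liver")
    cortex_sl = layout.region_slices("cortex")
    refl_sl = layout.region_slices("reflector")
    var[liver_sl] = params.echogenicity_ratio * v[liver_sl]
    var[cortex_sl] = 1.0
    var[refl_sl] = REFLECTOR_VAR
    labels[liver_sl] = LIVER
    labels[cortex_sl] = RENAL_CORTEX
    labels[refl_sl] = REFLECTOR
    return TissueMap(var, labels, params.heterogeneity_tau,
                     params.correlation_length_mm, layout)


def _psf_sigmas_px(params: SimulationParams):
    sig_ax = params.psf_axial_fwhm_mm * _FWHM_TO_SIGMA / params.pixel_spacing_y_mm
    sig_lat = params.psf_lateral_fwhm_mm * _FWHM_TO_SIGMA / params.pixel_spacing_x_mm
    return sig_ax, sig_lat


def simulate_envelope(tissue: TissueMap, params: SimulationParams,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Echo envelope (pre-compression) for one speckle realization."""
    if not np.any(tissue.echogenicity > 0):
        raise DegenerateInputError("all-zero tissue map: envelope is zero "
                                   "everywhere and cannot be log-compressed")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape = tissue.echogenicity.shape
    amp = np.sqrt(tissue.echogenicity / 2.0)
    f = amp * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    sig_ax, sig_lat = _psf_sigmas_px(params)
    f = (ndimage.gaussian_filter(f.real, (sig_ax, sig_lat))
         + 1j * ndimage.gaussian_filter(f.imag, (sig_ax, sig_lat)))
    if params.coherence_extra_px > 0:
        se = params.coherence_extra_px
        fs = (ndimage.gaussian_filter(f.real, se)
              + 1j * ndimage.gaussian_filter(f.imag, se))
        liver = tissue.region_labels == LIVER
        p0 = np.mean(np.abs(f[liver]) ** 2)
        p1 = np.mean(np.abs(fs[liver]) ** 2)
        fs *= np.sqrt(p0 / p1)
        f = np.where(liver, fs, f)
    return np.abs(f)


def envelope_to_display(env: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Log-compress an envelope to 8-bit display levels.

    ``g = 20 log10(env / max(env))`` clipped to ``[-DR, 0]`` and mapped
    linearly to ``[0, 255]``.  Referencing the per-image maximum mirrors a
    fixed-gain display and couples absolute brightness to the strongest
    specular structure in the frame.
    """
    dr = float(dynamic_range_db)
    with np.errstate(divide="ignore"):
        gdb = 20.0 * np.log10(env / env.max())
    disp = np.round(np.clip(gdb + dr, 0.0, dr) * 255.0 / dr)
    return disp.astype(np.uint8)


def simulate_bmode(tissue: TissueMap, params: SimulationParams,
                   rng: np.random.Generator | None = None) -> BModeImage:
    """One simulated B-mode frame; bit-reproducible given the seed."""
    env = simulate_envelope(tissue, params, rng)
    pixels = envelope_to_display(env, params.dynamic_range_db)
    meta = {"simulated": True, "grade": params.grade, "seed": params.seed,
            "dynamic_range_db": params.dynamic_range_db}
    return BModeImage(pixels, params.pixel_spacing_x_mm,
                      params.pixel_spacing_y_mm, meta)


def simulate_grade_image(grade: int, seed: int = 0, size: int = 256,
                         rng: np.random.Generator | None = None):
    """Convenience wrapper: tissue map + frame for one steatosis grade.

    Returns ``(image, layout)``.  A single generator is threaded through
    tissue construction and scattering so the whole frame is a deterministic
    function of ``(grade, seed, size)``.
    """
    params = params_for_grade(grade, seed=seed)
    layout = default_layout(size)
    if rng is None:
        rng = np.random.default_rng(seed)
    tissue = make_tissue_map(params, layout, rng=rng)
    image = simulate_bmode(tissue, params, rng=rng)
    return image, layout


def standard_rois(layout: Layout, area_px: int = 100):
    """The measurement ROIs for a simulated frame: four liver disks (one per
    'lobe view') and one renal-cortex disk, all of the conventional
    100-pixel area."""
    liver = [make_circular_roi(c, r, area_px) for r, c in layout.liver_roi_centers]
    rr, rc = layout.cortex_roi_center
    return liver, make_circular_roi(rc, rr, area_px)
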