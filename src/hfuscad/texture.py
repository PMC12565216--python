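"""Gray-level co-occurrence matrix and the four second-order texture features.

Conventions (the source tooling's aggregation style): ordered pixel pairs at
distance 1 along the four 2D directions (0,1), (1,0), (1,1), (1,-1) are
pooled into a single matrix before normalization, counting each pair in both
orientations (symmetric GLCM); pairs with either pixel outside the ROI mask
are excluded.  Gray-level indices are 0-based and sum entropy uses log base
2 (bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


class EmptyGLCMError(ValueError):
    """Raised when no valid in-mask pixel pair exists."""


@dataclass
class GLCM:
    p: np.ndarray
    n_gray_levels: int
    distance_px: int
    directions: tuple
    symmetric: bool = True


@dataclass
class TextureFeatures:
    """The four GLCM features.

    contrast     sum_ij p(i,j) (i-j)^2        local gray-level variation
    correlation  cov(i,j) / (sigma_x sigma_y) linear dependency; NaN when a
                                              single level is occupied
    energy       sum_ij p(i,j)^2              uniformity (angular second
                                              moment)
    sum_entropy  -sum_k p_{x+y}(k) log2 p_{x+y}(k), randomness of the
                                              diagonal-sum marginal
    """

    contrast: float
    correlation: float
    energy: float
    sum_entropy: float

    def as_dict(self):
        return {"contrast": self.contrast, "correlation": self.correlation,
                "energy": self.energy, "sum_entropy": self.sum_entropy}


def build_glcm(levels: np.ndarray, mask: np.ndarray | None = None,
               distance_px: int = 1,
               directions: tuple = DEFAULT_DIRECTIONS,
               n_gray_levels: int | None = None) -> GLCM:
    """Accumulate the pooled symmetric co-occurrence matrix.

    ``levels`` is an integer grid; ``mask`` selects ROI pixels (all pixels
    when None).  Counts for offset (dy, dx) and its reverse are both
    accumulated, the directions pooled, and the matrix normalized to sum 1.
    """
    levels = np.asarray(levels)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    if n_gray_levels is None:
        n_gray_levels = int(levels[mask].max()) + 1 if mask.any() else 1
    ng = int(n_gray_levels)
    grid = np.where(mask, levels, -1).astype(np.intp)
    h, w = grid.shape
    p = np.zeros((ng, ng))
    for dy0, dx0 in directions:
        dy, dx = dy0 * distance_px, dx0 * distance_px
        ay0, ay1 = max(0, -dy), h - max(0, dy)
        ax0, ax1 = max(0, -dx), w - max(0, dx)
        if ay1 <= ay0 or ax1 <= ax0:
            continue
        a = grid[ay0:ay1, ax0:ax1]
        b = grid[ay0 + dy:ay1 + dy, ax0 + dx:ax1 + dx]
        ok = (a >= 0) & (b >= 0)
        np.add.at(p, (a[ok], b[ok]), 1.0)
        np.add.at(p, (b[ok], a[ok]), 1.0)
    total = p.sum()
    if total == 0:
        raise EmptyGLCMError("no valid in-mask pixel pair at the requested "
                             "distance/directions")
    return GLCM(p / total, ng, distance_px, tuple(directions), True)


def texture_features(glcm: GLCM) -> TextureFeatures:
    """Evaluate the four features on a normalized GLCM.

    Marginal means/SDs come from the row marginal; for a symmetric matrix
    mu_x = mu_y by construction.  With a single occupied gray level the
    correlation denominator vanishes and correlation is reported as NaN.
    """
    p = glcm.p
    ng = glcm.n_gray_levels
    i = np.arange(ng, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sig_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    energy = float((p * p).sum())
    if sig_x * sig_y == 0:
        correlation = float("nan")
    else:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y)
                            / (sig_x * sig_y))

    p_sum = np.zeros(2 * ng - 1)
    ri, ci = np.nonzero(p)
    np.add.at(p_sum, ri + ci, p[ri, ci])
    nz = p_sum > 0
    sum_entropy = float(-(p_sum[nz] * np.log2(p_sum[nz])).sum())
    return TextureFeatures(contrast, correlation, energy, sum_entropy)


@dataclass
class SubjectFeatures:
    """Per-animal feature means over the scanned lobe images."""

    contrast: float
    correlation: float
    energy: float
    sum_entropy: float
    n_images: int
    n_undefined_correlation: int


def features_for_subject(per_lobe: list[TextureFeatures]) -> SubjectFeatures:
    """Arithmetic mean per feature over lobe images; NaN correlations are
    excluded from the correlation mean and counted."""
    if not per_lobe:
        raise ValueError("at least one lobe feature set is required")
    contrast = float(np.mean([f.contrast for f in per_lobe]))
    energy = float(np.mean([f.energy for f in per_lobe]))
    sum_entropy = float(np.mean([f.sum_entropy for f in per_lobe]))
    corrs = [f.correlation for f in per_lobe if not np.isnan(f.correlation)]
    n_undef = len(per_lobe) - len(corrs)
    correlation = float(np.mean(corrs)) if corrs else float("nan")
    return SubjectFeatures(contrast, correlation, energy, sum_entropy,
                           len(per_lobe), n_undef)
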