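"""CUS/SSS score models and the study's statistical layer.

Covers the semiquantitative ultrasound score (CUS), the histological
steatosis severity score (SSS) with its severity classes, binary screening
metrics against the histological reference, max-of-healthy data-derived
cutoffs, tie-corrected Spearman correlation with Fisher-z confidence
intervals, Bonferroni multiplicity control, min-max feature normalization
and group percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# score models

@dataclass(frozen=True)
class CUSScore:
    """Visual ultrasound score: parenchymal echotexture grade (0-3) +
    liver-vs-renal-cortex relative echogenicity (0 lower / 1 equal /
    2 higher) + ascites (0/1); total 0-6."""

    parenchyma: int
    relative_echogenicity: int
    ascites: int

    def __post_init__(self):
        if not 0 <= self.parenchyma <= 3:
            raise ValueError("parenchyma grade must be 0-3")
        if not 0 <= self.relative_echogenicity <= 2:
            raise ValueError("relative echogenicity must be 0-2")
        if self.ascites not in (0, 1):
            raise ValueError("ascites must be 0 or 1")

    @property
    def total(self) -> int:
        return self.parenchyma + self.relative_echogenicity + self.ascites


@dataclass(frozen=True)
class SSSScore:
    """Histological steatosis severity score: macrovesicular (0-3) +
    microvesicular (0-3) + hepatocyte hypertrophy (0-3); total 0-9."""

    macro: int
    micro: int
    hypertrophy: int

    def __post_init__(self):
        for name in ("macro", "micro", "hypertrophy"):
            v = getattr(self, name)
            if not 0 <= v <= 3:
                raise ValueError(f"{name} score must be 0-3")

    @property
    def total(self) -> int:
        return self.macro + self.micro + self.hypertrophy


class SeverityClass(NamedTuple):
    code: int           # 0 none, 1 mild, 2 moderate, 3 severe
    label: str
    out_of_table: bool  # totals 8-9 are arithmetically possible but outside
                        # the published class table

SEVERITY_LABELS = {0: "none", 1: "mild", 2: "moderate", 3: "severe"}


def sss_class(score: "SSSScore | int") -> SeverityClass:
    """Severity class from the SSS total: 0 none, 1-2 mild, 3-4 moderate,
    5-7 severe; 8-9 map to severe with an out-of-table flag."""
    total = score.total if isinstance(score, SSSScore) else int(score)
    if total < 0:
        raise ValueError("SSS total must be non-negative")
    if total == 0:
        code, flag = 0, False
    elif total <= 2:
        code, flag = 1, False
    elif total <= 4:
        code, flag = 2, False
    elif total <= 7:
        code, flag = 3, False
    elif total <= 9:
        code, flag = 3, True
    else:
        raise ValueError("SSS total must be <= 9")
    return SeverityClass(code, SEVERITY_LABELS[code], flag)


def cus_positive(score: "CUSScore | int") -> bool:
    """Binary positivity: any nonzero CUS component (total >= 1)."""
    total = score.total if isinstance(score, CUSScore) else int(score)
    return total >= 1


# ---------------------------------------------------------------------------
# screening

@dataclass(frozen=True)
class ScreeningResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _rate(num, den):
    return num / den if den > 0 else float("nan")


def screening_metrics(truth: Sequence[bool],
                      predicted: Sequence[bool]) -> ScreeningResult:
    """Confusion counts and the four screening rates.

    ``truth`` is the histological reference (steatosis present), ``predicted``
    the imaging call.  Rates with a zero denominator are reported as NaN.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and prediction must be equal-length and "
                         "non-empty")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    return ScreeningResult(
        tp, fp, tn, fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=_rate(tp + tn, t.size),
        ppv=_rate(tp, tp + fp),
    )


def derive_cutoff(values: Sequence[float], reference: Sequence[bool]) -> float:
    """Max-of-healthy cutoff: the maximum of ``values`` over the reference
    (e.g. SSS = 0) subset.  The classification rule is strictly greater-than,
    so every reference value classifies negative and specificity on the
    reference set is 1 by construction."""
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=bool)
    if not reference.any():
        raise ValueError("reference subset is empty")
    return float(values[reference].max())


def classify_by_cutoff(values: Sequence[float], cutoff: float) -> np.ndarray:
    """Positive iff value > cutoff (strict)."""
    return np.asarray(values, dtype=float) > cutoff


def indeterminate_zone(values: Sequence[float],
                       truth: Sequence[bool]) -> tuple[float, float, bool]:
    """Overlap interval of the two classes: (min over diseased, max over
    healthy, empty_flag).  The interval is empty when the classes separate
    (low > high)."""
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not truth.any() or truth.all():
        raise ValueError("both classes must be represented")
    low = float(values[truth].min())
    high = float(values[~truth].max())
    return low, high, low > high


# ---------------------------------------------------------------------------
# correlation and multiplicity

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    significant: bool
    alpha: float


class UndefinedCorrelationError(ValueError):
    """Raised when either vector has zero rank variance."""


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x: Sequence[float], y: Sequence[float], n_tests: int = 1,
             family_alpha: float = 0.05) -> CorrelationResult:
    """Tie-corrected Spearman correlation with t-approximate p value and
    Fisher-z 95% confidence interval.

    Ranks use average ranking for ties; r is the Pearson correlation of the
    rank vectors; ``p`` comes from ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2``
    degrees of freedom; the CI uses ``atanh(r) +/- z_{.975}/sqrt(n-3)``.
    Significance is assessed at the Bonferroni-adjusted level
    ``family_alpha / n_tests``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedCorrelationError("zero rank variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    zcrit = stats.norm.ppf(0.975)
    if abs(r) >= 1.0 or n <= 3:
        ci_low = ci_high = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci_low = float(np.tanh(z - zcrit * se))
        ci_high = float(np.tanh(z + zcrit * se))
    alpha = bonferroni_alpha(family_alpha, n_tests)
    return CorrelationResult(r, n, ci_low, ci_high, p, p < alpha, alpha)


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test threshold ``family_alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# normalization and summaries

def minmax_normalize(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Map values to [0, 1] by (v - min) / (max - min); a constant vector
    maps to all 0.5 with a degenerate flag."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.full_like(v, 0.5), True
    return (v - vmin) / (vmax - vmin), False


def percent_change(reference: float, test: float) -> float:
    """Percent difference of a test-group mean versus a reference-group
    mean: ``(test/reference - 1) x 100``."""
    if reference == 0:
        raise ZeroDivisionError("zero reference mean")
    return (test / reference - 1.0) * 100.0
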