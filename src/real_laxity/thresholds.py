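"""Distribution summaries, normality assessment and SD-based threshold derivation.

The category limits of the REAL classification are not arbitrary: if the
mediolateral laxity differences are normally distributed, ±1 SD and ±2 SD
bands around the mean partition the cohort into three natural severity
groups. The observed difference SDs (2.72 mm in extension, 2.98 mm in
flexion — both "slightly over 2.5 mm") are floored to a 0.5 mm grid and the
minimum across positions taken as the first limit; the second limit doubles
it, mirroring the ±2 SD construction. That yields the canonical 2.5 / 5.0 mm
scheme.

Normality is assessed with the Lilliefors variant of the Kolmogorov–Smirnov
test (mean and SD estimated from the sample, p-values capped at 0.2 as in
the classic table) together with the Shapiro–Wilk test; a sample is called
normal only if both tests fail to reject at the chosen alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .core import LaxityValidationError, ThresholdScheme

__all__ = [
    "DistributionSummary",
    "NormalityReport",
    "SdBandSpec",
    "summarize",
    "assess_normality",
    "derive_threshold_scheme",
    "sd_bands",
    "LILLIEFORS_P_CAP",
]

#: Classic Lilliefors tables do not resolve p beyond 0.2; larger values are
#: reported as 0.2 (the convention behind printed "p = 0.2" results).
LILLIEFORS_P_CAP: float = 0.2

#: Smallest sample size for a stable Shapiro–Wilk statistic.
_MIN_N_NORMALITY: int = 8


def _as_finite_array(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise LaxityValidationError("values must all be finite")
    return arr


@dataclass(frozen=True)
class DistributionSummary:
    """Sample size, mean, sample SD (n−1) and boxplot-rule outlier count."""

    n: int
    mean: float
    sd: float
    outlier_count: int


@dataclass(frozen=True)
class NormalityReport:
    """Lilliefors-KS and Shapiro–Wilk results with the joint verdict."""

    ks_statistic: float
    ks_p: float
    sw_statistic: float
    sw_p: float
    alpha: float
    is_normal: bool


@dataclass(frozen=True)
class SdBandSpec:
    """Symmetric ±1 SD / ±2 SD bands about a distribution mean.

    ``band1`` is the central (mean−SD, mean+SD) interval; ``band2`` the two
    flanking intervals out to ±2 SD; ``band3`` everything beyond. Together
    they partition the real line.
    """

    center: float
    sd: float

    @property
    def band1(self) -> tuple[float, float]:
        return (self.center - self.sd, self.center + self.sd)

    @property
    def band2(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (self.center - 2 * self.sd, self.center - self.sd),
            (self.center + self.sd, self.center + 2 * self.sd),
        )

    @property
    def band3_edges(self) -> tuple[float, float]:
        """Outer edges: band 3 is (−inf, lower) ∪ (upper, +inf)."""
        return (self.center - 2 * self.sd, self.center + 2 * self.sd)

    def band_of(self, x: float) -> int:
        z = abs(x - self.center) / self.sd
        if z < 1.0:
            return 1
        if z <= 2.0:
            return 2
        return 3


def summarize(values: Sequence[float], outlier_fence: float = 1.5) -> DistributionSummary:
    """Sample mean, sample SD (n−1 denominator) and boxplot-rule outliers.

    Outliers are values beyond ``Q1 − fence·IQR`` or ``Q3 + fence·IQR`` with
    linear-interpolation quartiles; the fence multiplier (default 1.5, the
    Tukey rule) is configurable.
    """
    arr = _as_finite_array(values)
    if arr.size < 2:
        raise LaxityValidationError("insufficient data: need at least 2 values")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - outlier_fence * iqr, q3 + outlier_fence * iqr
    outliers = int(np.count_nonzero((arr < lo) | (arr > hi)))
    return DistributionSummary(n=int(arr.size), mean=mean, sd=sd, outlier_count=outliers)


def assess_normality(values: Sequence[float], alpha: float = 0.05) -> NormalityReport:
    """Joint Lilliefors-KS + Shapiro–Wilk normality assessment.

    The KS variant estimates mean and SD from the sample (Lilliefors) and
    caps its p-value at 0.2; the verdict ``is_normal`` is True only when
    both p-values exceed ``alpha``.
    """
    arr = _as_finite_array(values)
    if arr.size < _MIN_N_NORMALITY:
        raise LaxityValidationError(
            f"need at least {_MIN_N_NORMALITY} values for normality assessment, got {arr.size}"
        )
    if np.ptp(arr) == 0:
        raise LaxityValidationError("degenerate sample: all values equal")
    ks_stat, ks_p = _lilliefors(arr, dist="norm")
    ks_p = min(float(ks_p), LILLIEFORS_P_CAP)
    sw_stat, sw_p = stats.shapiro(arr)
    is_normal = bool(ks_p > alpha and sw_p > alpha)
    return NormalityReport(
        ks_statistic=float(ks_stat),
        ks_p=ks_p,
        sw_statistic=float(sw_stat),
        sw_p=float(sw_p),
        alpha=float(alpha),
        is_normal=is_normal,
    )


def derive_threshold_scheme(sds: Sequence[float], grid_mm: float = 0.5) -> ThresholdScheme:
    """Derive the category limits from per-position difference SDs.

    Each SD is floored to the ``grid_mm`` grid ("slightly over 2.5 mm"
    becomes 2.5); the first limit is the minimum of the floored values and
    the second limit doubles it. Order of the input SDs is irrelevant.
    """
    if grid_mm <= 0 or not math.isfinite(grid_mm):
        raise LaxityValidationError("grid_mm must be positive and finite")
    sds = [float(s) for s in sds]
    if not sds:
        raise LaxityValidationError("need at least one SD")
    for s in sds:
        if not math.isfinite(s) or s <= 0:
            raise LaxityValidationError(f"SDs must be positive and finite, got {s!r}")
    # floor to grid; guard against float wobble at exact grid points (3.0 / 0.5)
    eps = 1e-9
    floored = [math.floor(s / grid_mm + eps) * grid_mm for s in sds]
    limit1 = min(floored)
    if limit1 <= 0:
        raise LaxityValidationError(
            f"derived limit is not positive (SDs {sds} on a {grid_mm} mm grid)"
        )
    return ThresholdScheme(limit1_mm=limit1, limit2_mm=2.0 * limit1)


def sd_bands(summary: DistributionSummary) -> SdBandSpec:
    """The ±1/±2 SD band partition about the sample mean (precursor of the
    rounded threshold scheme)."""
    if summary.sd <= 0:
        raise LaxityValidationError("sd must be positive to define SD bands")
    return SdBandSpec(center=summary.mean, sd=summary.sd)
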