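"""Synthetic knee-laxity cohort generator.

Emulates the distributional structure the analysis assumes, so every
pipeline stage is testable without clinical data:

* extension difference ~ Normal(0.54, 2.72) mm, extension sum ~
  Normal(5.33, 2.38) mm;
* flexion difference ~ Normal(0.203, 2.98) mm; flexion sum right-skewed
  (moment-matched shifted gamma, mean 6.57, SD 3.26 mm) so that its
  normality test rejects at large n while the differences pass;
* demographics: age ~ Normal(69.6, 8.69) years, 89/120 female, 103/120
  varus, 51.7% left knees;
* end-of-surgery phenotypes drawn from a configurable mixture (defaults:
  the published final-assessment frequencies) with 0.5–3 mm residual
  per-compartment laxity.

Compartment laxities must be non-negative, i.e. the mediolateral difference
d is confined to [−s, s] where s is the mediolateral sum. Naive
accept/reject of knees with a negative compartment would truncate the joint
distribution and bias the sum mean upward by ~0.5 mm under the default
parameters. Instead the generator samples exactly from truncated laws via
inverse-CDF transforms — the sum truncated at zero, the difference
truncated to [−s, s] given the drawn s — with the proposal mean/SD
calibrated by root-finding so the *post-truncation* marginal moments equal
the configured ones. Moment recovery is then exact up to Monte-Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .core import (
    FLEXION_CODES,
    KneeLaxityProfile,
    LaxityPair,
    LaxityValidationError,
    PHENOTYPE_LABELS,
    round_half_up,
)
from .pipeline import KneeRecord

__all__ = [
    "GeneratorParams",
    "default_phase1_params",
    "default_phase2_params",
    "generate_cohort",
    "generate_final_states",
    "TABLE3_FINAL_MIXTURE",
]

#: Published end-of-surgery phenotype frequencies (counts over 102 knees).
TABLE3_FINAL_MIXTURE: dict[str, float] = {
    "1A": 70 / 102,
    "1B": 23 / 102,
    "1C": 5 / 102,
    "2A": 2 / 102,
    "2B": 1 / 102,
    "2C": 1 / 102,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Cohort-generator parameterization; defaults are the phase-1 study values."""

    n: int = 120
    seed: int = 0
    ext_diff: tuple[float, float] = (0.54, 2.72)     # (mean, sd) mm
    flex_diff: tuple[float, float] = (0.203, 2.98)
    ext_sum: tuple[float, float] = (5.33, 2.38)
    flex_sum: tuple[float, float] = (6.57, 3.26)
    flex_sum_shift: float = 1.0                      # gamma location (mm)
    age: tuple[float, float] = (69.6, 8.69)          # years
    p_female: float = 89 / 120
    p_left: float = 62 / 120                         # 51.7% left knees
    p_varus: float = 103 / 120
    final_state_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE3_FINAL_MIXTURE)
    )
    residual_laxity_range: tuple[float, float] = (0.5, 3.0)   # mm, lesser side
    resolution_mm: float = 0.1                       # display rounding

    def __post_init__(self) -> None:
        if self.n < 1:
            raise LaxityValidationError("n must be >= 1")
        for name in ("ext_diff", "flex_diff", "ext_sum", "flex_sum", "age"):
            mean, sd = getattr(self, name)
            if not (math.isfinite(mean) and math.isfinite(sd) and sd > 0):
                raise LaxityValidationError(f"{name} must have finite mean and sd > 0")
        for pos in ("ext", "flex"):
            m_sum = getattr(self, f"{pos}_sum")[0]
            m_diff = getattr(self, f"{pos}_diff")[0]
            if m_sum < abs(m_diff):
                raise LaxityValidationError(
                    f"infeasible {pos} parameters: mean sum {m_sum} < |mean diff| {abs(m_diff)}"
                )
        if self.flex_sum[0] <= self.flex_sum_shift:
            raise LaxityValidationError("flex_sum mean must exceed flex_sum_shift")
        for name in ("p_female", "p_left", "p_varus"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise LaxityValidationError(f"{name} must lie in [0, 1]")
        mix = dict(self.final_state_mixture)
        unknown = set(mix) - set(PHENOTYPE_LABELS)
        if unknown:
            raise LaxityValidationError(f"mixture has unknown labels: {sorted(unknown)}")
        if any(p < 0 for p in mix.values()):
            raise LaxityValidationError("mixture probabilities must be >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise LaxityValidationError(
                f"final_state_mixture must sum to 1, got {sum(mix.values())!r}"
            )
        lo, hi = self.residual_laxity_range
        if not 0 <= lo < hi:
            raise LaxityValidationError("residual_laxity_range must be 0 <= lo < hi")


def default_phase1_params(n: int = 120, seed: int = 0) -> GeneratorParams:
    """The derivation-phase parameterization (published means/SDs verbatim)."""
    return GeneratorParams(n=n, seed=seed)


def default_phase2_params(n: int = 102, seed: int = 0) -> GeneratorParams:
    """The validation-phase cohort size with phase-2 demographics."""
    return GeneratorParams(
        n=n,
        seed=seed,
        age=(71.7, 9.68),
        p_female=73 / 99,
        p_left=38 / 102,
        p_varus=89 / 102,
    )


# ---------------------------------------------------------------------------
# truncated-normal moment machinery (vectorized closed forms)

def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _truncnorm_mean_var(
    m: float, s: float, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of N(m, s²) truncated to [lo, hi] (finite bounds)."""
    a = (lo - m) / s
    b = (hi - m) / s
    z = ndtr(b) - ndtr(a)
    z = np.maximum(z, 1e-300)
    pa, pb = _phi(a), _phi(b)
    ratio = (pa - pb) / z
    mean = m + s * ratio
    var = s * s * (1.0 + (a * pa - b * pb) / z - ratio * ratio)
    return mean, var


@lru_cache(maxsize=64)
def _calibrate_nonneg_normal(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Proposal (m, s) such that N(m, s²) truncated to [0, ∞) has the target
    mean and SD."""
    hi = target_mean + 12.0 * target_sd   # numerically +inf for the truncation

    def eqs(x: np.ndarray) -> list[float]:
        m, s = x
        if s <= 0:
            return [1e6, 1e6]
        mean, var = _truncnorm_mean_var(m, s, np.array(0.0), np.array(hi))
        return [float(mean) - target_mean, math.sqrt(float(var)) - target_sd]

    sol, info, ier, msg = optimize.fsolve(
        eqs, [target_mean, target_sd], full_output=True
    )
    if ier != 1 or max(abs(v) for v in info["fvec"]) > 1e-8:
        raise LaxityValidationError(
            f"sum-moment calibration failed for mean={target_mean}, sd={target_sd}: {msg}"
        )
    return float(sol[0]), float(sol[1])


def _quadrature_nodes(
    kind: str, a: float, b: float, lo: float, hi: float, n_nodes: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights for ∫ p(s)·f(s) ds over the s-support.

    ``kind`` selects the sum density p: "truncnorm" (params a=m, b=s,
    support [lo, hi]) or "gamma" (a=shape, b=scale, location lo).
    """
    x, w = leggauss(n_nodes)
    nodes = 0.5 * (hi - lo) * (x + 1.0) + lo
    scale = 0.5 * (hi - lo)
    if kind == "truncnorm":
        al, bl = (lo - a) / b, np.inf
        pdf = stats.truncnorm.pdf(nodes, al, bl, loc=a, scale=b)
    elif kind == "gamma":
        pdf = stats.gamma.pdf(nodes, a, loc=lo, scale=b)
    else:  # pragma: no cover
        raise ValueError(kind)
    return nodes, w * scale * pdf


@lru_cache(maxsize=64)
def _calibrate_banded_diff(
    target_mean: float,
    target_sd: float,
    sum_kind: str,
    sum_a: float,
    sum_b: float,
    sum_lo: float,
    sum_hi: float,
) -> tuple[float, float]:
    """Proposal (m, s) such that, with the sum S drawn from the configured
    law and D | S ~ N(m, s²) truncated to [−S, S], the marginal of D has the
    target mean and SD."""
    nodes, weights = _quadrature_nodes(sum_kind, sum_a, sum_b, sum_lo, sum_hi)

    def moments(m: float, s: float) -> tuple[float, float]:
        mean_c, var_c = _truncnorm_mean_var(m, s, -nodes, nodes)
        e1 = float(np.sum(weights * mean_c))
        e2 = float(np.sum(weights * (var_c + mean_c * mean_c)))
        return e1, math.sqrt(max(e2 - e1 * e1, 0.0))

    def eqs(x: np.ndarray) -> list[float]:
        m, s = x
        if s <= 0:
            return [1e6, 1e6]
        e1, sd = moments(m, s)
        return [e1 - target_mean, sd - target_sd]

    sol, info, ier, msg = optimize.fsolve(
        eqs, [target_mean, 1.3 * target_sd], full_output=True
    )
    if ier != 1 or max(abs(v) for v in info["fvec"]) > 1e-7:
        raise LaxityValidationError(
            f"difference-moment calibration failed for mean={target_mean}, "
            f"sd={target_sd}: {msg}"
        )
    return float(sol[0]), float(sol[1])


def _gamma_shape_scale(mean: float, sd: float, shift: float) -> tuple[float, float]:
    if mean <= shift:
        raise LaxityValidationError("gamma mean must exceed the shift")
    excess = mean - shift
    return (excess / sd) ** 2, sd * sd / excess


def _draw_truncated_diff(
    rng: np.random.Generator, s: np.ndarray, m: float, sig: float
) -> np.ndarray:
    """Exact inverse-CDF draw of N(m, sig²) truncated to [−s, s] per element."""
    lo_u = ndtr((-s - m) / sig)
    hi_u = ndtr((s - m) / sig)
    u = rng.uniform(lo_u, hi_u)
    return m + sig * ndtri(u)


def _round_grid(x: np.ndarray, resolution: float) -> np.ndarray:
    # half-up on non-negative values
    return np.floor(x / resolution + 0.5) * resolution


# ---------------------------------------------------------------------------
# public generator API

def _draw_position(
    rng: np.random.Generator,
    n: int,
    sum_moments: tuple[float, float],
    diff_moments: tuple[float, float],
    gamma_shift: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (sum, diff) for one knee position with non-negative compartments."""
    sm, ssd = sum_moments
    dm, dsd = diff_moments
    if gamma_shift is None:
        m, s = _calibrate_nonneg_normal(sm, ssd)
        hi = sm + 12.0 * ssd
        u = rng.uniform(ndtr((0.0 - m) / s), ndtr((hi - m) / s), size=n)
        sums = m + s * ndtri(u)
        md, sd_ = _calibrate_banded_diff(dm, dsd, "truncnorm", m, s, 0.0, hi)
    else:
        shape, scale = _gamma_shape_scale(sm, ssd, gamma_shift)
        sums = gamma_shift + rng.gamma(shape, scale, size=n)
        hi = sm + 14.0 * ssd
        md, sd_ = _calibrate_banded_diff(dm, dsd, "gamma", shape, scale, gamma_shift, hi)
    diffs = _draw_truncated_diff(rng, sums, md, sd_)
    return sums, diffs


def generate_cohort(
    params: GeneratorParams,
    timepoints: Literal["initial", "both"] = "initial",
) -> list[KneeRecord]:
    """Generate a synthetic cohort; deterministic under ``params`` (incl. seed).

    Per knee, (sum, difference) is drawn per position and the compartments
    reconstructed as medial = (sum+diff)/2, lateral = (sum−diff)/2, then
    rounded half-up to the display resolution. With ``timepoints="both"``
    end-of-surgery profiles are added from the configured phenotype mixture.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n

    ext_s, ext_d = _draw_position(rng, n, params.ext_sum, params.ext_diff, None)
    flex_s, flex_d = _draw_position(
        rng, n, params.flex_sum, params.flex_diff, params.flex_sum_shift
    )

    res = params.resolution_mm
    ext_med = _round_grid((ext_s + ext_d) / 2.0, res)
    ext_lat = _round_grid((ext_s - ext_d) / 2.0, res)
    flex_med = _round_grid((flex_s + flex_d) / 2.0, res)
    flex_lat = _round_grid((flex_s - flex_d) / 2.0, res)

    ages = np.clip(rng.normal(params.age[0], params.age[1], size=n), 18.0, 105.0)
    female = rng.uniform(size=n) < params.p_female
    left = rng.uniform(size=n) < params.p_left
    varus = rng.uniform(size=n) < params.p_varus

    width = max(4, len(str(n)))
    cohort = [
        KneeRecord(
            id=f"K{i + 1:0{width}d}",
            initial=KneeLaxityProfile(
                extension=LaxityPair(float(ext_med[i]), float(ext_lat[i])),
                flexion=LaxityPair(float(flex_med[i]), float(flex_lat[i])),
            ),
            age=round(float(ages[i]), 1),
            sex="F" if female[i] else "M",
            side="L" if left[i] else "R",
            deformity="varus" if varus[i] else "valgus",
        )
        for i in range(n)
    ]
    if timepoints == "both":
        cohort = generate_final_states(cohort, params, seed=(params.seed + 1) % 2**31)
    elif timepoints != "initial":
        raise LaxityValidationError(f"timepoints must be 'initial' or 'both', got {timepoints!r}")
    return cohort


# per-category |difference| sampling ranges, margin-protected so that 0.1 mm
# display rounding of the two compartments cannot move a knee across a band
# edge (rounding perturbs the difference by at most ±0.1 mm)
_CATEGORY_DIFF_RANGES: dict[int, tuple[float, float]] = {
    1: (0.0, 2.35),
    2: (2.65, 4.85),
    3: (5.15, 8.0),
}


def _sample_pair_for_category(
    rng: np.random.Generator,
    category: int,
    residual_range: tuple[float, float],
    resolution: float,
) -> LaxityPair:
    lo, hi = _CATEGORY_DIFF_RANGES[category]
    d_abs = rng.uniform(lo, hi)
    lesser = rng.uniform(*residual_range)
    greater = lesser + d_abs
    if rng.uniform() < 0.5:
        medial, lateral = greater, lesser
    else:
        medial, lateral = lesser, greater
    return LaxityPair(
        round_half_up(medial, resolution), round_half_up(lateral, resolution)
    )


def generate_final_states(
    cohort: Sequence[KneeRecord], params: GeneratorParams, seed: int
) -> list[KneeRecord]:
    """Attach end-of-surgery profiles sampled from the phenotype mixture.

    Each knee's final label is drawn from ``params.final_state_mixture``
    (independently of its initial state — a phenomenological balancing
    model, not a biomechanical one); laxities realizing the label are drawn
    uniformly inside the label's difference bands with the lesser
    compartment in the residual-laxity range.
    """
    mix = dict(params.final_state_mixture)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise LaxityValidationError("final_state_mixture must sum to 1")
    labels = sorted(mix)
    probs = np.array([mix[lab] for lab in labels])
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(labels), size=len(cohort), p=probs / probs.sum())
    out: list[KneeRecord] = []
    for record, idx in zip(cohort, drawn):
        label = labels[idx]
        ext_cat, flex_cat = int(label[0]), FLEXION_CODES.index(label[1]) + 1
        final = KneeLaxityProfile(
            extension=_sample_pair_for_category(
                rng, ext_cat, params.residual_laxity_range, params.resolution_mm
            ),
            flexion=_sample_pair_for_category(
                rng, flex_cat, params.residual_laxity_range, params.resolution_mm
            ),
        )
        out.append(replace(record, final=final))
    return out
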