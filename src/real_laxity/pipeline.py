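"""Phase-1 and phase-2 cohort pipelines.

Phase 1 (derivation): summarize the sums and differences of medial/lateral
laxity in extension and flexion, assess their normality, derive the
SD-based threshold scheme from the *difference* distributions that passed
normality, and tabulate the initial phenotype distribution.

Phase 2 (validation): classify every knee at the start and end of surgery
under a FIXED scheme (no re-derivation), tabulate both distributions and
the 9×9 initial→final transition table, and compute the percentage of knees
ending inside the balanced area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Sequence

from scipy import stats as _scipy_stats

from .core import (
    BalancedAreaPolicy,
    KneeLaxityProfile,
    LaxityValidationError,
    PHENOTYPE_LABELS,
    ThresholdScheme,
    classify,
    laxity_sum,
    signed_difference,
)
from .thresholds import (
    DistributionSummary,
    NormalityReport,
    assess_normality,
    derive_threshold_scheme,
    summarize,
)

__all__ = [
    "KneeRecord",
    "PhenotypeDistribution",
    "TransitionTable",
    "Phase1Report",
    "Phase2Report",
    "phenotype_distribution",
    "balanced_percentage",
    "transition_table",
    "compare_phase_distributions",
    "run_phase1",
    "run_phase2",
    "percent_half_up",
]

Timepoint = Literal["initial", "final"]


def percent_half_up(count: float, n: float, decimals: int = 1) -> float:
    """100·count/n rounded half-up to the given number of decimals."""
    if n <= 0:
        raise LaxityValidationError("n must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100.0 * count / n).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KneeRecord:
    """One knee: initial laxity profile, optional end-of-surgery profile,
    optional demographics."""

    id: str
    initial: KneeLaxityProfile
    final: KneeLaxityProfile | None = None
    age: float | None = None
    sex: str | None = None          # "F" / "M"
    side: str | None = None         # "L" / "R"
    deformity: str | None = None    # "varus" / "valgus"

    def profile(self, timepoint: Timepoint) -> KneeLaxityProfile:
        if timepoint == "initial":
            return self.initial
        if timepoint == "final":
            if self.final is None:
                raise LaxityValidationError(f"record {self.id!r} has no final profile")
            return self.final
        raise LaxityValidationError(f"unknown timepoint {timepoint!r}")


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Counts and one-decimal percentages over the nine phenotype labels."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = {label: int(self.counts.get(label, 0)) for label in PHENOTYPE_LABELS}
        unknown = set(self.counts) - set(PHENOTYPE_LABELS)
        if unknown:
            raise LaxityValidationError(f"unknown phenotype labels: {sorted(unknown)}")
        if any(c < 0 for c in counts.values()):
            raise LaxityValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        n = self.n
        if n == 0:
            raise LaxityValidationError("empty distribution has no percentages")
        return {label: percent_half_up(c, n) for label, c in self.counts.items()}

    def percentage_vector(self) -> list[float]:
        pct = self.percentages
        return [pct[label] for label in PHENOTYPE_LABELS]


@dataclass(frozen=True)
class TransitionTable:
    """9×9 counts of initial → final phenotype labels."""

    counts: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        counts = {
            ini: {fin: int(self.counts.get(ini, {}).get(fin, 0)) for fin in PHENOTYPE_LABELS}
            for ini in PHENOTYPE_LABELS
        }
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return sum(sum(row.values()) for row in self.counts.values())

    def initial_marginal(self) -> PhenotypeDistribution:
        return PhenotypeDistribution(
            {ini: sum(row.values()) for ini, row in self.counts.items()}
        )

    def final_marginal(self) -> PhenotypeDistribution:
        return PhenotypeDistribution(
            {
                fin: sum(self.counts[ini][fin] for ini in PHENOTYPE_LABELS)
                for fin in PHENOTYPE_LABELS
            }
        )


def _classify_cohort(
    cohort: Sequence[KneeRecord], timepoint: Timepoint, scheme: ThresholdScheme
) -> list[str]:
    if not cohort:
        raise LaxityValidationError("empty cohort")
    if timepoint == "final":
        missing = [r.id for r in cohort if r.final is None]
        if missing:
            raise LaxityValidationError(
                f"records missing final profiles: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    return [classify(r.profile(timepoint), scheme).label for r in cohort]


def phenotype_distribution(
    cohort: Sequence[KneeRecord],
    timepoint: Timepoint = "initial",
    scheme: ThresholdScheme | None = None,
) -> PhenotypeDistribution:
    """Tabulate the REAL phenotype distribution of a cohort at one timepoint."""
    scheme = scheme or ThresholdScheme()
    labels = _classify_cohort(cohort, timepoint, scheme)
    counts = {label: 0 for label in PHENOTYPE_LABELS}
    for lab in labels:
        counts[lab] += 1
    return PhenotypeDistribution(counts)


def balanced_percentage(
    dist: PhenotypeDistribution, policy: BalancedAreaPolicy | None = None
) -> float:
    """Percentage of knees whose label lies in the balanced area (one decimal)."""
    policy = policy or BalancedAreaPolicy()
    if dist.n == 0:
        raise LaxityValidationError("empty distribution")
    in_area = sum(dist.counts[label] for label in policy.balanced_area)
    return percent_half_up(in_area, dist.n)


def transition_table(
    cohort: Sequence[KneeRecord], scheme: ThresholdScheme | None = None
) -> TransitionTable:
    """9×9 initial→final phenotype transition counts."""
    scheme = scheme or ThresholdScheme()
    initial_labels = _classify_cohort(cohort, "initial", scheme)
    final_labels = _classify_cohort(cohort, "final", scheme)
    counts: dict[str, dict[str, int]] = {
        ini: {fin: 0 for fin in PHENOTYPE_LABELS} for ini in PHENOTYPE_LABELS
    }
    for ini, fin in zip(initial_labels, final_labels):
        counts[ini][fin] += 1
    return TransitionTable(counts)


def compare_phase_distributions(
    d1: PhenotypeDistribution, d2: PhenotypeDistribution
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of two 9-vectors of percentages."""
    v1, v2 = d1.percentage_vector(), d2.percentage_vector()
    if len(set(v1)) == 1 or len(set(v2)) == 1:
        raise LaxityValidationError("zero variance in a percentage vector")
    r, p = _scipy_stats.pearsonr(v1, v2)
    return float(r), float(p)


@dataclass(frozen=True)
class Phase1Report:
    """Everything the derivation phase produces."""

    summaries: Mapping[str, DistributionSummary]      # keys like "extension_difference"
    normality: Mapping[str, NormalityReport]
    scheme: ThresholdScheme
    distribution: PhenotypeDistribution
    derived_from: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class Phase2Report:
    """Everything the validation phase produces, under a frozen scheme."""

    scheme: ThresholdScheme
    policy: BalancedAreaPolicy
    initial_distribution: PhenotypeDistribution
    final_distribution: PhenotypeDistribution
    transitions: TransitionTable
    balanced_percentage: float


_CHANNELS = (
    ("extension_difference", "extension", signed_difference),
    ("extension_sum", "extension", laxity_sum),
    ("flexion_difference", "flexion", signed_difference),
    ("flexion_sum", "flexion", laxity_sum),
)


def run_phase1(
    cohort: Sequence[KneeRecord],
    alpha: float = 0.05,
    grid_mm: float = 0.5,
) -> Phase1Report:
    """Derivation pipeline: summaries → normality → scheme → distribution.

    The scheme is derived from the sample SDs of the mediolateral
    *differences* only, restricted to positions whose difference passed the
    joint normality assessment; sums are summarized and tested but never
    drive thresholds.
    """
    if not cohort:
        raise LaxityValidationError("empty cohort")
    if len(cohort) < 2:
        raise LaxityValidationError("insufficient data: need at least 2 knees")
    values = {
        key: [fn(getattr(r.initial, position)) for r in cohort]
        for key, position, fn in _CHANNELS
    }
    summaries = {key: summarize(vals) for key, vals in values.items()}
    normality = {key: assess_normality(vals, alpha=alpha) for key, vals in values.items()}

    candidates = [
        key
        for key in ("extension_difference", "flexion_difference")
        if normality[key].is_normal
    ]
    if not candidates:
        raise LaxityValidationError(
            "no mediolateral difference distribution passed normality; "
            "SD-based categorization is not justified"
        )
    scheme = derive_threshold_scheme([summaries[k].sd for k in candidates], grid_mm=grid_mm)
    dist = phenotype_distribution(cohort, "initial", scheme)
    return Phase1Report(
        summaries=summaries,
        normality=normality,
        scheme=scheme,
        distribution=dist,
        derived_from=tuple(candidates),
    )


def run_phase2(
    cohort: Sequence[KneeRecord],
    scheme: ThresholdScheme | None = None,
    policy: BalancedAreaPolicy | None = None,
) -> Phase2Report:
    """Validation pipeline under a frozen threshold scheme."""
    scheme = scheme or ThresholdScheme()
    policy = policy or BalancedAreaPolicy()
    initial = phenotype_distribution(cohort, "initial", scheme)
    final = phenotype_distribution(cohort, "final", scheme)
    transitions = transition_table(cohort, scheme)
    pct = balanced_percentage(final, policy)
    return Phase2Report(
        scheme=scheme,
        policy=policy,
        initial_distribution=initial,
        final_distribution=final,
        transitions=transitions,
        balanced_percentage=pct,
    )
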