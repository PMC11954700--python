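"""Core REAL (Robotic Evaluation of Articular Laxity) domain types and rules.

The REAL classification assigns an intraoperative knee to one of nine
soft-tissue laxity phenotypes. In each of two knee positions (full extension
and 90° flexion) the medial and lateral compartment laxities are measured in
millimetres under varus/valgus stress; the *absolute* mediolateral difference
is banded at two limits (default 2.5 mm and 5.0 mm) into three ordinal
categories — coded 1/2/3 in extension and A/B/C in flexion — and the two
codes concatenate into the phenotype label (``"1A"`` … ``"3C"``).

The signed difference (medial − lateral, positive = more medial laxity) is
retained for distribution statistics only; classification depends solely on
its magnitude, so swapping the compartments never changes the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "MAX_LAXITY_MM",
    "EXTENSION_CODES",
    "FLEXION_CODES",
    "PHENOTYPE_LABELS",
    "LaxityValidationError",
    "LaxityPair",
    "KneeLaxityProfile",
    "ThresholdScheme",
    "RealPhenotype",
    "BalanceTier",
    "BalancedAreaPolicy",
    "signed_difference",
    "laxity_sum",
    "categorize_abs_difference",
    "classify",
    "balance_tier",
    "is_in_balanced_area",
    "round_half_up",
]

#: Sanity bound on a single compartment laxity. Clinical openings beyond
#: 30 mm are not physiological and almost certainly data errors.
MAX_LAXITY_MM: float = 30.0

EXTENSION_CODES: tuple[str, ...] = ("1", "2", "3")
FLEXION_CODES: tuple[str, ...] = ("A", "B", "C")
#: The nine labels in grid order (extension-major, Table layout order).
PHENOTYPE_LABELS: tuple[str, ...] = tuple(
    e + f for e in EXTENSION_CODES for f in FLEXION_CODES
)


class LaxityValidationError(ValueError):
    """Raised when a laxity measurement violates its invariants."""


def _check_laxity(value: float, name: str, max_mm: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise LaxityValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise LaxityValidationError(f"{name} must be >= 0 mm, got {value}")
    if value > max_mm:
        raise LaxityValidationError(
            f"{name} = {value} mm exceeds the sanity bound of {max_mm} mm"
        )
    return value


def round_half_up(value: float, resolution: float = 0.1) -> float:
    """Round to a grid with ties going away from zero (half-up).

    Banker's rounding (Python's built-in) would map 2.25 -> 2.2 at 0.1 mm
    resolution; clinical displays round half-up, so 2.25 -> 2.3.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    scaled = value / resolution
    return math.floor(abs(scaled) + 0.5) * math.copysign(resolution, value)


@dataclass(frozen=True)
class LaxityPair:
    """Medial and lateral compartment laxity (mm) at one knee position."""

    medial_mm: float
    lateral_mm: float
    max_mm: float = MAX_LAXITY_MM

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "medial_mm", _check_laxity(self.medial_mm, "medial_mm", self.max_mm)
        )
        object.__setattr__(
            self, "lateral_mm", _check_laxity(self.lateral_mm, "lateral_mm", self.max_mm)
        )

    def swapped(self) -> "LaxityPair":
        return LaxityPair(self.lateral_mm, self.medial_mm, self.max_mm)


@dataclass(frozen=True)
class KneeLaxityProfile:
    """Extension and 90°-flexion laxity pairs for one knee at one timepoint."""

    extension: LaxityPair
    flexion: LaxityPair

    def __post_init__(self) -> None:
        for name in ("extension", "flexion"):
            if not isinstance(getattr(self, name), LaxityPair):
                raise LaxityValidationError(f"{name} must be a LaxityPair")


@dataclass(frozen=True)
class ThresholdScheme:
    """The two category limits of the classification.

    ``limit1_mm`` separates category 1/A from 2/B; ``limit2_mm`` separates
    2/B from 3/C. By construction ``limit2 = 2 * limit1`` (mirroring the
    ±1 SD / ±2 SD band derivation) unless explicitly overridden.
    """

    limit1_mm: float = 2.5
    limit2_mm: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.limit1_mm) and self.limit1_mm > 0):
            raise LaxityValidationError("limit1_mm must be a positive finite number")
        limit2 = 2.0 * self.limit1_mm if self.limit2_mm is None else float(self.limit2_mm)
        if not (math.isfinite(limit2) and limit2 > self.limit1_mm):
            raise LaxityValidationError("limit2_mm must exceed limit1_mm")
        object.__setattr__(self, "limit2_mm", limit2)


@dataclass(frozen=True)
class RealPhenotype:
    """One of the nine REAL labels (extension category × flexion category)."""

    extension_category: int
    flexion_category: str

    def __post_init__(self) -> None:
        if str(self.extension_category) not in EXTENSION_CODES:
            raise LaxityValidationError(
                f"extension_category must be 1, 2 or 3, got {self.extension_category!r}"
            )
        if self.flexion_category not in FLEXION_CODES:
            raise LaxityValidationError(
                f"flexion_category must be A, B or C, got {self.flexion_category!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.extension_category}{self.flexion_category}"

    @classmethod
    def from_label(cls, label: str) -> "RealPhenotype":
        if label not in PHENOTYPE_LABELS:
            raise LaxityValidationError(f"unknown phenotype label {label!r}")
        return cls(int(label[0]), label[1])


class BalanceTier(str, Enum):
    BALANCED = "balanced"
    ALMOST_BALANCED = "almost_balanced"
    UNBALANCED = "unbalanced"


def _as_label_set(labels: Iterable[str]) -> frozenset[str]:
    labels = frozenset(labels)
    unknown = labels - set(PHENOTYPE_LABELS)
    if unknown:
        raise LaxityValidationError(f"unknown phenotype labels: {sorted(unknown)}")
    return labels


@dataclass(frozen=True)
class BalancedAreaPolicy:
    """Which end-of-surgery phenotypes count as (almost) balanced.

    Default: 1A balanced; 1B and 2A almost balanced. The union is the
    "balanced area". An alternative reading groups only 1A+1B; it is
    available as :meth:`abstract_variant`.
    """

    balanced_labels: frozenset[str] = field(default_factory=lambda: frozenset({"1A"}))
    almost_balanced_labels: frozenset[str] = field(
        default_factory=lambda: frozenset({"1B", "2A"})
    )

    def __post_init__(self) -> None:
        balanced = _as_label_set(self.balanced_labels)
        almost = _as_label_set(self.almost_balanced_labels)
        if balanced & almost:
            raise LaxityValidationError(
                "balanced and almost-balanced label sets must be disjoint"
            )
        object.__setattr__(self, "balanced_labels", balanced)
        object.__setattr__(self, "almost_balanced_labels", almost)

    @property
    def balanced_area(self) -> frozenset[str]:
        return self.balanced_labels | self.almost_balanced_labels

    @classmethod
    def abstract_variant(cls) -> "BalancedAreaPolicy":
        """1A balanced, 1B almost balanced (no 2A)."""
        return cls(frozenset({"1A"}), frozenset({"1B"}))


def signed_difference(pair: LaxityPair) -> float:
    """Medial − lateral laxity in mm (positive = more medial laxity)."""
    return pair.medial_mm - pair.lateral_mm


def laxity_sum(pair: LaxityPair) -> float:
    """Medial + lateral laxity in mm (total mediolateral envelope)."""
    return pair.medial_mm + pair.lateral_mm


def categorize_abs_difference(d_abs: float, scheme: ThresholdScheme | None = None) -> int:
    """Band an absolute mediolateral difference into ordinal category 1, 2 or 3.

    Bands are [0, limit1), [limit1, limit2], (limit2, inf): a difference of
    exactly 2.5 mm falls in category 2, exactly 5.0 mm also in category 2,
    matching the printed "< 2.5", "2.5–5" and "> 5" bands.
    """
    scheme = scheme or ThresholdScheme()
    d_abs = float(d_abs)
    if not math.isfinite(d_abs) or d_abs < 0:
        raise LaxityValidationError(f"d_abs must be finite and >= 0, got {d_abs!r}")
    if d_abs < scheme.limit1_mm:
        return 1
    if d_abs <= scheme.limit2_mm:
        return 2
    return 3


def classify(profile: KneeLaxityProfile, scheme: ThresholdScheme | None = None) -> RealPhenotype:
    """Assign the REAL phenotype of one knee profile under a threshold scheme."""
    scheme = scheme or ThresholdScheme()
    ext_cat = categorize_abs_difference(abs(signed_difference(profile.extension)), scheme)
    flex_cat = categorize_abs_difference(abs(signed_difference(profile.flexion)), scheme)
    return RealPhenotype(ext_cat, FLEXION_CODES[flex_cat - 1])


def balance_tier(
    phenotype: RealPhenotype | str, policy: BalancedAreaPolicy | None = None
) -> BalanceTier:
    """Tier of a phenotype under a balanced-area policy."""
    policy = policy or BalancedAreaPolicy()
    label = phenotype if isinstance(phenotype, str) else phenotype.label
    if label not in PHENOTYPE_LABELS:
        raise LaxityValidationError(f"unknown phenotype label {label!r}")
    if label in policy.balanced_labels:
        return BalanceTier.BALANCED
    if label in policy.almost_balanced_labels:
        return BalanceTier.ALMOST_BALANCED
    return BalanceTier.UNBALANCED


def is_in_balanced_area(
    phenotype: RealPhenotype | str, policy: BalancedAreaPolicy | None = None
) -> bool:
    return balance_tier(phenotype, policy) is not BalanceTier.UNBALANCED
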