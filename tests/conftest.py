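from __future__ import annotations

from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

import pytest

from real_laxity import KneeLaxityProfile, KneeRecord, LaxityPair, PhenotypeDistribution
from real_laxity.core import PHENOTYPE_LABELS

# representative |medial − lateral| difference per ordinal category,
# comfortably inside each band
_CATEGORY_DIFF = {1: 1.0, 2: 3.0, 3: 6.0}


def pair_for_category(category: int) -> LaxityPair:
    d = _CATEGORY_DIFF[category]
    return LaxityPair(1.0 + d, 1.0)


def profile_for_label(label: str) -> KneeLaxityProfile:
    """A laxity profile that classifies to the given label under the default
    2.5/5.0 mm scheme."""
    ext_cat = int(label[0])
    flex_cat = "ABC".index(label[1]) + 1
    return KneeLaxityProfile(
        extension=pair_for_category(ext_cat), flexion=pair_for_category(flex_cat)
    )


def cohort_from_counts(counts: dict[str, int], with_final: bool = False) -> list[KneeRecord]:
    """A cohort whose initial classification realizes the given label counts."""
    records = []
    i = 0
    for label in PHENOTYPE_LABELS:
        for _ in range(counts.get(label, 0)):
            i += 1
            profile = profile_for_label(label)
            records.append(
                KneeRecord(
                    id=f"S{i:04d}",
                    initial=profile,
                    final=profile if with_final else None,
                )
            )
    return records


def cohort_from_transitions(pairs: list[tuple[str, str]]) -> list[KneeRecord]:
    """A cohort realizing the given (initial label, final label) pairs."""
    return [
        KneeRecord(
            id=f"T{i:04d}",
            initial=profile_for_label(ini),
            final=profile_for_label(fin),
        )
        for i, (ini, fin) in enumerate(pairs, start=1)
    ]


_LABELS = ("1A", "1B", "1C", "2A", "2B", "2C", "3A", "3B", "3C")

#: Published initial-assessment counts, derivation cohort (n=120).
TABLE2_COUNTS = dict(zip(_LABELS, (54, 19, 3, 20, 13, 3, 2, 4, 2)))
#: Published initial-assessment counts, validation cohort (n=102).
TABLE3_INITIAL_COUNTS = dict(zip(_LABELS, (43, 24, 2, 12, 10, 8, 0, 1, 2)))
#: Published final-assessment counts, validation cohort (n=102).
TABLE3_FINAL_COUNTS = dict(zip(_LABELS, (70, 23, 5, 2, 1, 1, 0, 0, 0)))


@pytest.fixture
def table2_distribution() -> PhenotypeDistribution:
    return PhenotypeDistribution(TABLE2_COUNTS)


@pytest.fixture
def table3_final_distribution() -> PhenotypeDistribution:
    return PhenotypeDistribution(TABLE3_FINAL_COUNTS)


@pytest.fixture
def table3_initial_distribution() -> PhenotypeDistribution:
    return PhenotypeDistribution(TABLE3_INITIAL_COUNTS)
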