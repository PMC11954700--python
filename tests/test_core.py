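"""The classification rule: bands, grid, balanced area, validation."""

from __future__ import annotations

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from real_laxity.core import (
    BalanceTier,
    BalancedAreaPolicy,
    KneeLaxityProfile,
    LaxityPair,
    LaxityValidationError,
    PHENOTYPE_LABELS,
    RealPhenotype,
    ThresholdScheme,
    balance_tier,
    categorize_abs_difference,
    classify,
    is_in_balanced_area,
    laxity_sum,
    round_half_up,
    signed_difference,
)

laxity_values = st.floats(min_value=0.0, max_value=30.0, allow_nan=False)


@pytest.mark.parametrize(
    "medial, lateral, expected",
    [(3.0, 3.0, 0.0), (4.0, 1.5, 2.5), (1.0, 4.0, -3.0)],
)
def test_signed_difference_is_medial_minus_lateral(medial, lateral, expected):
    assert signed_difference(LaxityPair(medial, lateral)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "medial, lateral, expected",
    [(0.0, 0.0, 0.0), (3.0, 2.3, 5.3), (4.0, 2.6, 6.6)],
)
def test_laxity_sum(medial, lateral, expected):
    assert laxity_sum(LaxityPair(medial, lateral)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "d_abs, expected",
    [
        (0.0, 1),
        (2.4, 1),
        (2.5, 2),   # band edges belong to the middle category
        (3.0, 2),
        (5.0, 2),
        (5.01, 3),
        (6.0, 3),
    ],
)
def test_band_edges_and_interiors(d_abs, expected):
    assert categorize_abs_difference(d_abs) == expected


def test_band_oracle_equivalence_on_decimal_grid():
    """Band assignment equals brute-force interval membership on a 0.1 mm grid."""
    scheme = ThresholdScheme()
    for i in range(0, 101):
        d = i / 10.0
        if 0 <= d < scheme.limit1_mm:
            expected = 1
        elif scheme.limit1_mm <= d <= scheme.limit2_mm:
            expected = 2
        else:
            expected = 3
        assert categorize_abs_difference(d, scheme) == expected


@given(
    d1=st.floats(min_value=0, max_value=15, allow_nan=False),
    d2=st.floats(min_value=0, max_value=15, allow_nan=False),
    limit1=st.floats(min_value=0.5, max_value=5, allow_nan=False),
)
def test_banding_is_monotone_in_difference(d1, d2, limit1):
    scheme = ThresholdScheme(limit1_mm=limit1)
    lo, hi = sorted([d1, d2])
    assert categorize_abs_difference(lo, scheme) <= categorize_abs_difference(hi, scheme)


@pytest.mark.parametrize(
    "ext, flex, expected",
    [
        ((2.0, 1.0), (2.0, 1.5), "1A"),
        ((5.0, 1.0), (2.0, 2.0), "2A"),
        ((8.0, 1.0), (9.0, 2.0), "3C"),
    ],
)
def test_classify_published_grid_examples(ext, flex, expected):
    profile = KneeLaxityProfile(extension=LaxityPair(*ext), flexion=LaxityPair(*flex))
    assert classify(profile).label == expected


@given(em=laxity_values, el=laxity_values, fm=laxity_values, fl=laxity_values)
def test_classify_total_and_side_swap_invariant(em, el, fm, fl):
    """Every valid profile gets exactly one of the nine labels, and the label
    ignores which compartment is medial."""
    profile = KneeLaxityProfile(LaxityPair(em, el), LaxityPair(fm, fl))
    swapped = KneeLaxityProfile(LaxityPair(el, em), LaxityPair(fl, fm))
    label = classify(profile).label
    assert label in PHENOTYPE_LABELS
    assert classify(swapped).label == label


def test_phenotype_label_round_trip():
    for label in PHENOTYPE_LABELS:
        assert RealPhenotype.from_label(label).label == label
    with pytest.raises(LaxityValidationError):
        RealPhenotype.from_label("4A")
    with pytest.raises(LaxityValidationError):
        RealPhenotype(0, "A")


@pytest.mark.parametrize(
    "label, tier",
    [
        ("1A", BalanceTier.BALANCED),
        ("1B", BalanceTier.ALMOST_BALANCED),
        ("2A", BalanceTier.ALMOST_BALANCED),
        ("2B", BalanceTier.UNBALANCED),
        ("3C", BalanceTier.UNBALANCED),
    ],
)
def test_default_balanced_area_tiers(label, tier):
    assert balance_tier(label) is tier
    assert is_in_balanced_area(label) == (tier is not BalanceTier.UNBALANCED)


def test_abstract_policy_variant_excludes_2a():
    policy = BalancedAreaPolicy.abstract_variant()
    assert balance_tier("1B", policy) is BalanceTier.ALMOST_BALANCED
    assert balance_tier("2A", policy) is BalanceTier.UNBALANCED


def test_policy_sets_must_be_disjoint_and_known():
    with pytest.raises(LaxityValidationError):
        BalancedAreaPolicy(frozenset({"1A"}), frozenset({"1A"}))
    with pytest.raises(LaxityValidationError):
        BalancedAreaPolicy(frozenset({"9Z"}), frozenset())


@pytest.mark.parametrize("medial, lateral", [(-1.0, 2.0), (2.0, float("nan")), (31.0, 2.0)])
def test_invalid_laxities_rejected(medial, lateral):
    with pytest.raises(LaxityValidationError):
        LaxityPair(medial, lateral)


def test_invalid_schemes_rejected():
    with pytest.raises(LaxityValidationError):
        ThresholdScheme(limit1_mm=0.0)
    with pytest.raises(LaxityValidationError):
        ThresholdScheme(limit1_mm=3.0, limit2_mm=2.0)
    with pytest.raises(LaxityValidationError):
        categorize_abs_difference(-0.1)


def test_scheme_defaults_double_the_first_limit():
    assert ThresholdScheme(limit1_mm=2.0).limit2_mm == pytest.approx(4.0)
    custom = ThresholdScheme(limit1_mm=2.0, limit2_mm=6.0)
    assert custom.limit2_mm == pytest.approx(6.0)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(2.25, 0.1) == pytest.approx(2.3)
    assert round_half_up(2.24, 0.1) == pytest.approx(2.2)
    assert math.copysign(1, round_half_up(-2.25, 0.1)) == -1
    assert abs(round_half_up(-2.25, 0.1)) == pytest.approx(2.3)
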