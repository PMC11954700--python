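"""Distribution summaries, normality assessment and threshold derivation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from real_laxity.core import LaxityValidationError
from real_laxity.thresholds import (
    LILLIEFORS_P_CAP,
    assess_normality,
    derive_threshold_scheme,
    sd_bands,
    summarize,
)


class TestSummarize:
    def test_closed_form_examples(self):
        s = summarize([1, 2, 3])
        assert s.n == 3
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)

    def test_constant_sample(self):
        s = summarize([5, 5, 5, 5])
        assert (s.mean, s.sd, s.outlier_count) == (5.0, 0.0, 0)

    def test_boxplot_rule_flags_extreme_value(self):
        s = summarize(list(range(1, 10)) + [100])
        assert s.outlier_count == 1

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=200))
    def test_matches_two_pass_textbook_computation(self, values):
        s = summarize(values)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert s.mean == pytest.approx(mean, abs=1e-9)
        assert s.sd == pytest.approx(math.sqrt(var), abs=1e-9)

    def test_errors(self):
        with pytest.raises(LaxityValidationError, match="insufficient"):
            summarize([1.0])
        with pytest.raises(LaxityValidationError):
            summarize([1.0, float("inf")])


class TestAssessNormality:
    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(2024)
        report = assess_normality(rng.normal(0, 1, 10_000))
        assert report.is_normal
        assert report.ks_p <= LILLIEFORS_P_CAP

    def test_large_exponential_sample_fails(self):
        rng = np.random.default_rng(2024)
        report = assess_normality(rng.exponential(1.0, 10_000))
        assert not report.is_normal
        assert report.sw_p < 0.05

    def test_verdict_requires_both_tests(self):
        rng = np.random.default_rng(7)
        report = assess_normality(rng.normal(0, 1, 500))
        assert report.is_normal == (report.ks_p > 0.05 and report.sw_p > 0.05)

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(LaxityValidationError, match="degenerate"):
            assess_normality([3.0] * 50)
        with pytest.raises(LaxityValidationError):
            assess_normality([1.0, 2.0, 3.0])


class TestDeriveThresholdScheme:
    @pytest.mark.parametrize(
        "sds, limit1, limit2",
        [
            ([2.72, 2.98], 2.5, 5.0),   # the study's phase-1 difference SDs
            ([2.0, 2.0], 2.0, 4.0),
            ([3.1, 2.6], 2.5, 5.0),
        ],
    )
    def test_floor_to_grid_then_minimum(self, sds, limit1, limit2):
        scheme = derive_threshold_scheme(sds)
        assert scheme.limit1_mm == pytest.approx(limit1)
        assert scheme.limit2_mm == pytest.approx(limit2)

    @given(st.lists(st.floats(0.6, 10.0), min_size=1, max_size=6), st.randoms())
    def test_order_invariant(self, sds, rnd):
        shuffled = list(sds)
        rnd.shuffle(shuffled)
        assert derive_threshold_scheme(sds) == derive_threshold_scheme(shuffled)

    @given(st.lists(st.integers(1, 20), min_size=1, max_size=6))
    def test_on_grid_sds_give_their_minimum_exactly(self, halves):
        sds = [h * 0.5 for h in halves]
        assert derive_threshold_scheme(sds).limit1_mm == pytest.approx(min(sds))

    def test_invalid_inputs(self):
        with pytest.raises(LaxityValidationError):
            derive_threshold_scheme([])
        with pytest.raises(LaxityValidationError):
            derive_threshold_scheme([-1.0, 2.0])
        with pytest.raises(LaxityValidationError):
            derive_threshold_scheme([2.72], grid_mm=0.0)
        with pytest.raises(LaxityValidationError):
            # floors to zero: no positive limit exists on this grid
            derive_threshold_scheme([0.3], grid_mm=0.5)


class TestSdBands:
    def test_unit_case(self):
        spec = sd_bands(summarize([-1.0, 0.0, 1.0]))
        assert spec.band1 == pytest.approx((-1.0, 1.0))
        assert spec.band3_edges == pytest.approx((-2.0, 2.0))

    def test_phase1_extension_difference_band(self):
        from real_laxity.thresholds import DistributionSummary, SdBandSpec

        spec = sd_bands(DistributionSummary(n=120, mean=0.54, sd=2.72, outlier_count=1))
        assert spec.band1 == pytest.approx((-2.18, 3.26))

    @given(
        x=st.floats(-100, 100),
        mean=st.floats(-10, 10),
        sd=st.floats(0.1, 10),
    )
    def test_bands_partition_the_line(self, x, mean, sd):
        from real_laxity.thresholds import SdBandSpec

        spec = SdBandSpec(center=mean, sd=sd)
        band = spec.band_of(x)
        z = abs(x - mean) / sd
        assert band == (1 if z < 1 else 2 if z <= 2 else 3)

    def test_zero_sd_is_degenerate(self):
        with pytest.raises(LaxityValidationError):
            sd_bands(summarize([5, 5, 5]))
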