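"""Unit and property tests for WGD timing classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from tumorevo.timing import (
    CopyNumberSegment,
    RegionProfile,
    VariantObservation,
    classify_timing_point,
    integer_cn_state,
    proportion_ci,
    time_driver_multi_region,
    time_variant_single_region,
    variant_copy_number,
)


def wilson_cc_oracle(x: int, n: int, confidence: float) -> tuple[float, float]:
    """Continuity-corrected Wilson bounds found by root-finding: the limit p
    solves |p_hat - p| - 1/(2n) = z * sqrt(p(1-p)/n)."""
    z = norm.ppf(1 - (1 - confidence) / 2)
    p_hat = x / n

    def lower_eq(p):
        return (p_hat - p - 1 / (2 * n)) - z * math.sqrt(p * (1 - p) / n)

    def upper_eq(p):
        return (p - p_hat - 1 / (2 * n)) - z * math.sqrt(p * (1 - p) / n)

    low = 0.0 if x == 0 else brentq(lower_eq, 1e-12, p_hat, xtol=1e-13)
    high = 1.0 if x == n else brentq(upper_eq, p_hat, 1 - 1e-12, xtol=1e-13)
    return low, high


class TestProportionCI:
    def test_zero_successes_lower_bound_is_zero(self):
        low, high = proportion_ci(0, 100, 0.95)
        assert low == 0.0 and 0 < high < 0.1

    def test_all_successes_upper_bound_is_one(self):
        low, high = proportion_ci(100, 100, 0.95)
        assert high == 1.0 and 0.9 < low < 1

    @pytest.mark.parametrize("x,n", [(50, 100), (5, 12), (330, 1000), (1, 7), (399, 400)])
    def test_matches_independent_root_finding_oracle(self, x, n):
        got = proportion_ci(x, n, 0.95)
        want = wilson_cc_oracle(x, n, 0.95)
        assert got == pytest.approx(want, abs=1e-9)

    def test_interval_contains_point_estimate(self):
        for x, n in [(3, 10), (0, 5), (5, 5), (250, 800)]:
            low, high = proportion_ci(x, n)
            assert low <= x / n <= high

    def test_rejects_zero_depth(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


class TestVariantCopyNumber:
    def test_pure_diploid_heterozygous(self):
        assert variant_copy_number(0.5, 1.0, 2) == pytest.approx(1.0)

    def test_one_of_four_copies_at_purity_one(self):
        assert variant_copy_number(0.25, 1.0, 4) == pytest.approx(1.0)

    def test_admixture_formula(self):
        assert variant_copy_number(0.33, 0.5, 2) == pytest.approx(1.32)

    def test_rejects_zero_purity(self):
        with pytest.raises(ValueError):
            variant_copy_number(0.3, 0.0, 2)


class TestIntegerCnState:
    @pytest.mark.parametrize("cn,total,want", [
        (1.32, 2, 1), (0.2, 4, 1), (5.7, 4, 4), (1.5, 4, 2), (2.49, 4, 2)])
    def test_round_and_clamp(self, cn, total, want):
        assert integer_cn_state(cn, total) == want


def classify_oracle(cn_var, major, minor, n_wgd):
    """Independent re-statement of the timing rules, written as a flat
    decision list over the allele-tracking prose."""
    # allele tracking
    if minor == 0:
        allele = "major"
    elif cn_var > minor:
        allele = "major"
    else:
        allele = "minor"
    copies = major if allele == "major" else minor
    if copies <= 1:
        return "unclear"
    threshold_pre = 2 if n_wgd == 1 else 4
    if cn_var >= threshold_pre:
        return "pre"
    if cn_var == 1:
        return "post"
    return "unclear"  # only reachable for n_wgd == 2, states 2-3


class TestClassifyTimingPoint:
    def test_single_copy_on_doubled_segment_is_post(self):
        # one mutant copy on a 2+2 segment after one doubling
        assert classify_timing_point(1, 2, 2, 1)[0] == "post"

    def test_two_copies_with_loh_is_pre_on_major(self):
        timing, allele, reason = classify_timing_point(2, 2, 0, 1)
        assert (timing, allele, reason) == ("pre", "major", "LOH_MAJOR_TRACK")

    @pytest.mark.parametrize("args", [(1, 1, 1, 1), (1, 2, 1, 1)])
    def test_single_copy_tracked_allele_unclear(self, args):
        timing, allele, reason = classify_timing_point(*args)
        assert timing == "unclear" and allele == "minor"
        assert reason == "SINGLE_COPY_ALLELE"

    def test_two_wgd_intermediate_states_unclear(self):
        assert classify_timing_point(2, 3, 2, 2)[0] == "unclear"
        assert classify_timing_point(3, 3, 2, 2)[0] == "unclear"
        assert classify_timing_point(4, 4, 4, 2)[0] == "pre"
        assert classify_timing_point(1, 4, 4, 2)[0] == "post"

    def test_exhaustive_agreement_with_independent_oracle(self):
        """Full enumeration over all states with total copy number <= 8."""
        n_checked = 0
        for major in range(0, 9):
            for minor in range(0, major + 1):
                if major + minor > 8 or major == 0:
                    continue
                for n_wgd in (1, 2):
                    for cn_var in range(1, major + minor + 1):
                        got = classify_timing_point(cn_var, major, minor, n_wgd)[0]
                        assert got == classify_oracle(cn_var, major, minor, n_wgd), \
                            (cn_var, major, minor, n_wgd)
                        n_checked += 1
        assert n_checked > 100

    def test_either_allele_rule_is_more_conservative(self):
        # 3+1 segment, variant at 3 copies: timeable under the default rule,
        # refused under the stricter either-allele reading
        assert classify_timing_point(3, 3, 1, 1)[0] == "pre"
        assert classify_timing_point(3, 3, 1, 1, single_copy_rule="either")[0] == "unclear"

    def test_cn_var_above_total_rejected(self):
        with pytest.raises(ValueError):
            classify_timing_point(5, 2, 2, 1)


REGION_WGD = RegionProfile("R1", 0.5, 1)


class TestSingleRegionTiming:
    def test_non_wgd_region_always_non_wgd(self):
        obs = VariantObservation("v", "chr1", 100, 500, 1000)
        seg = CopyNumberSegment("chr1", 0, 10**6, 2, 2)
        call = time_variant_single_region(obs, seg, RegionProfile("R0", 0.9, 0))
        assert call.timing == "non_wgd" and call.reason == "NO_WGD_REGION"

    def test_post_wgd_call_from_both_bounds(self):
        # both interval ends give one mutant copy on a two-copy major allele
        obs = VariantObservation("v", "chr1", 100, 330, 1000)
        seg = CopyNumberSegment("chr1", 0, 10**6, 2, 0)
        call = time_variant_single_region(obs, seg, REGION_WGD)
        assert call.timing == "post"
        assert call.cn_var_low == call.cn_var_high == 1

    def test_bound_disagreement_is_unclear(self):
        # shallow depth: the interval straddles one vs several copies
        obs = VariantObservation("v", "chr1", 100, 5, 12)
        seg = CopyNumberSegment("chr1", 0, 10**6, 2, 1)
        call = time_variant_single_region(obs, seg, RegionProfile("R1", 0.4, 1))
        assert call.timing == "unclear" and call.reason == "BOUND_DISAGREEMENT"
        assert call.cn_var_low < call.cn_var_high

    def test_variant_outside_segment_reported_not_dropped(self):
        obs = VariantObservation("v", "chr2", 100, 300, 1000)
        seg = CopyNumberSegment("chr1", 0, 10**6, 2, 2)
        call = time_variant_single_region(obs, seg, REGION_WGD)
        assert call.timing == "unclear" and call.reason == "NO_SEGMENT"

    def test_determinism(self):
        obs = VariantObservation("v", "chr1", 100, 200, 800)
        seg = CopyNumberSegment("chr1", 0, 10**6, 2, 1)
        a = time_variant_single_region(obs, seg, REGION_WGD)
        b = time_variant_single_region(obs, seg, REGION_WGD)
        assert a == b

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        vaf=st.floats(0.02, 0.98),
        purity=st.floats(0.2, 1.0),
        major=st.integers(1, 4),
        minor=st.integers(0, 4),
        n_wgd=st.sampled_from([1, 2]),
    )
    def test_wider_interval_never_flips_pre_post(self, vaf, purity, major, minor, n_wgd):
        """Lowering depth (widening the CI) at fixed VAF can only move a
        call toward unclear, never between pre and post."""
        if minor > major:
            major, minor = minor, major
        seg = CopyNumberSegment("chr1", 0, 10**6, major, minor)
        region = RegionProfile("R1", purity, n_wgd)
        calls = set()
        for depth in (2000, 500, 100, 30):
            alt = int(round(vaf * depth))
            obs = VariantObservation("v", "chr1", 100, alt, depth)
            calls.add(time_variant_single_region(obs, seg, region).timing)
        assert not {"pre", "post"} <= calls

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        alt=st.integers(0, 400),
        purity=st.floats(0.1, 1.0),
        major=st.integers(1, 5),
        minor=st.integers(0, 5),
        n_wgd=st.sampled_from([1, 2]),
    )
    def test_pre_requires_multi_copy_tracked_allele(self, alt, purity, major, minor, n_wgd):
        if minor > major:
            major, minor = minor, major
        seg = CopyNumberSegment("chr1", 0, 10**6, major, minor)
        obs = VariantObservation("v", "chr1", 100, alt, 400)
        call = time_variant_single_region(obs, seg, RegionProfile("R1", purity, n_wgd))
        if call.timing == "pre":
            copies = major if call.tracked_allele == "major" else minor
            assert copies >= 2


class TestMultiRegionTiming:
    SEG = {"A": [CopyNumberSegment("chr1", 0, 10**6, 2, 0)],
           "B": [CopyNumberSegment("chr1", 0, 10**6, 2, 1)]}

    def test_presence_in_non_wgd_region_forces_pre(self):
        regions = [RegionProfile("A", 0.6, 1), RegionProfile("B", 0.6, 0)]
        obs = {"B": VariantObservation("v", "chr1", 100, 50, 400)}
        timing, reason = time_driver_multi_region(obs, self.SEG, regions)
        assert timing == "pre" and reason == "NON_WGD_REGION_PRESENCE"

    def test_any_region_pre_wins(self):
        regions = [RegionProfile("A", 0.6, 1), RegionProfile("B", 0.6, 1)]
        obs = {
            # ~2 copies on the 2+0 segment in A, ~1 copy on 2+1 in B
            "A": VariantObservation("v", "chr1", 100, 240, 400),
            "B": VariantObservation("v", "chr1", 100, 95, 400),
        }
        assert time_driver_multi_region(obs, self.SEG, regions)[0] == "pre"

    def test_single_region_degenerates_to_upper_bound_call(self):
        regions = [RegionProfile("A", 0.6, 1)]
        obs = {"A": VariantObservation("v", "chr1", 100, 100, 400)}
        timing, _ = time_driver_multi_region(obs, self.SEG, regions)
        assert timing == "post"

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            time_driver_multi_region({}, {}, [])
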