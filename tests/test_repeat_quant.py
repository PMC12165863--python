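"""Anchoring, triplet classification and sample summaries."""

import math
import random
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatedit.repeat_quant import (
    CAG_CBE,
    GAA_ABE,
    AnchorStatus,
    ReadCall,
    RepeatSpec,
    TripletClass,
    call_read,
    classify_triplet,
    expand_iupac,
    locate_tract,
    summarize,
)

ALL_TRIPLETS = ["".join(t) for t in product("ACGT", repeat=3)]


class TestSpecs:
    def test_pattern_expansion(self):
        assert expand_iupac("YAR") == {"CAG", "CAA", "TAG", "TAA"}
        assert expand_iupac("GRR") == {"GAA", "GAG", "GGA", "GGG"}

    def test_intended_sets(self):
        assert CAG_CBE.intended == {"CAA"}
        assert GAA_ABE.intended == {"GAG", "GGA", "GGG"}

    def test_sets_pairwise_disjoint(self, spec):
        assert not spec.intended & spec.byproducts
        assert spec.pure not in spec.intended | spec.byproducts

    def test_pure_must_match_pattern(self):
        with pytest.raises(ValueError, match="does not match"):
            RepeatSpec(name="bad", pure="CCC", pattern="YAR")

    def test_flanks_free_of_pattern_triplets(self, spec):
        # a flank remnant in a partially anchored read must not look edited
        matches = expand_iupac(spec.pattern)
        for flank in (spec.left_flank, spec.right_flank):
            for i in range(len(flank) - 2):
                assert flank[i : i + 3] not in matches


class TestClassifyTriplet:
    # hand-written truth table for both shipped strategies: every triplet
    # inside the IUPAC pattern is pure/intended/byproduct, all else other
    @pytest.mark.parametrize(
        "spec_obj,truth",
        [
            (
                CAG_CBE,
                {"CAG": "pure", "CAA": "intended", "TAG": "byproduct",
                 "TAA": "byproduct"},
            ),
            (
                GAA_ABE,
                {"GAA": "pure", "GAG": "intended", "GGA": "intended",
                 "GGG": "intended"},
            ),
        ],
        ids=["cag-cbe", "gaa-abe"],
    )
    def test_all_64_triplets(self, spec_obj, truth):
        for triplet in ALL_TRIPLETS:
            expected = truth.get(triplet, "other")
            assert classify_triplet(triplet, spec_obj).value == expected

    def test_n_base_is_other(self, spec):
        assert classify_triplet("NAA", spec) is TripletClass.OTHER

    def test_lowercase_accepted(self):
        assert classify_triplet("caa", CAG_CBE) is TripletClass.INTENDED

    @pytest.mark.parametrize("bad", ["CA", "CAGG", "CAX"])
    def test_invalid_triplets_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_triplet(bad, CAG_CBE)


class TestLocateTract:
    def test_both_anchored(self, spec):
        read = spec.left_flank + spec.pure * 4 + spec.right_flank
        status, tract, origin = locate_tract(read, spec)
        assert status is AnchorStatus.BOTH
        assert tract == spec.pure * 4
        assert origin == 0

    def test_left_only_long_repeat(self, spec):
        # a short read into a long tract never reaches the right flank
        read = (spec.left_flank + spec.pure * 200)[:150]
        status, tract, _ = locate_tract(read, spec)
        assert status is AnchorStatus.LEFT_ONLY
        assert tract == read[len(spec.left_flank):]

    def test_right_only_frame_from_right_edge(self, spec):
        # 2 extra bases upstream: triplets must stay in frame with the
        # right edge, dropping the leading partial triplet
        tract = spec.pure[1:] + spec.pure * 3
        read = tract + spec.right_flank
        status, found, origin = locate_tract(read, spec)
        assert status is AnchorStatus.RIGHT_ONLY
        assert found == tract
        assert origin == len(tract) % 3 == 2

    def test_unanchored_random_sequence(self, spec):
        rng = random.Random(0)
        read = "".join(rng.choice("ACGT") for _ in range(150))
        assert locate_tract(read, spec)[0] is AnchorStatus.UNANCHORED

    def test_mostly_n_read_unanchored(self, spec):
        read = spec.left_flank + "N" * 100
        assert locate_tract(read, spec)[0] is AnchorStatus.UNANCHORED


class TestCallRead:
    def test_direct_decomposition(self):
        read = CAG_CBE.left_flank + "CAGCAACAG" + CAG_CBE.right_flank
        call = call_read("r", read, CAG_CBE)
        assert (call.triplet_count, call.interruption_count) == (3, 1)
        assert call.pure_count == 2 and not call.has_indel_signal

    def test_gaa_two_interruptions(self):
        read = GAA_ABE.left_flank + "GAAGAGGGAGAA" + GAA_ABE.right_flank
        call = call_read("r", read, GAA_ABE)
        assert call.triplet_count == 4
        assert call.interruption_count == 2  # GAG + GGA
        assert dict(call.triplet_types) == {"GAA": 2, "GAG": 1, "GGA": 1}

    def test_indel_signal_on_out_of_frame_tract(self):
        read = CAG_CBE.left_flank + "CAGCA" + CAG_CBE.right_flank
        call = call_read("r", read, CAG_CBE)
        assert call.triplet_count == 1
        assert call.has_indel_signal

    def test_counts_partition(self, spec):
        rng = random.Random(1)
        tract = "".join(rng.choice(ALL_TRIPLETS) for _ in range(30))
        call = call_read("r", spec.left_flank + tract + spec.right_flank, spec)
        assert (
            call.pure_count + call.interruption_count
            + call.byproduct_count + call.other_count
        ) == call.triplet_count == 30

    def test_frame_robustness_left_vs_right_only(self, spec):
        # same in-frame tract anchored from either side gives identical calls
        tract = spec.pure * 5 + next(iter(spec.intended)) + spec.pure * 4
        left_call = call_read("l", spec.left_flank + tract, spec)
        right_call = call_read("r", tract + spec.right_flank, spec)
        assert left_call.anchor_status is AnchorStatus.LEFT_ONLY
        assert right_call.anchor_status is AnchorStatus.RIGHT_ONLY
        for attr in ("triplet_count", "interruption_count", "byproduct_count",
                     "other_count", "pure_count"):
            assert getattr(left_call, attr) == getattr(right_call, attr)


def _mk_call(interruptions, pure, byproducts=0, rid="r"):
    n = interruptions + pure + byproducts
    return ReadCall(
        read_id=rid,
        anchor_status=AnchorStatus.BOTH,
        triplet_count=n,
        interruption_count=interruptions,
        byproduct_count=byproducts,
        pure_count=pure,
    )


class TestSummarize:
    def test_edited_fraction_counting(self):
        calls = [_mk_call(1, 9) for _ in range(4)] + [_mk_call(0, 10) for _ in range(6)]
        s = summarize(calls, CAG_CBE)
        assert s.aligned_reads == 10
        assert s.edited_fraction == pytest.approx(0.4)
        assert s.triplet_fraction_interrupted == pytest.approx(4 / 100)

    def test_all_pure_gives_inf_purity(self):
        s = summarize([_mk_call(0, 10) for _ in range(5)], CAG_CBE)
        assert s.edited_fraction == 0.0
        assert s.triplet_fraction_interrupted == 0.0
        assert math.isinf(s.purity_ratio)

    def test_summary_statistics(self):
        calls = [_mk_call(2, 8), _mk_call(1, 9), _mk_call(0, 10, byproducts=0)]
        s = summarize(calls, CAG_CBE)
        assert s.mean_interruptions == pytest.approx(1.5)
        assert s.median_interruptions == pytest.approx(1.5)
        assert s.mean_interrupted_tract_fraction == pytest.approx(0.15)
        assert s.interruption_histogram == {1: 1, 2: 1}

    def test_f_le_fi_invariant(self):
        calls = [_mk_call(2, 8), _mk_call(0, 10), _mk_call(1, 19)]
        s = summarize(calls, CAG_CBE)
        assert 0.0 <= s.triplet_fraction_interrupted <= s.mean_interrupted_tract_fraction <= 1.0

    def test_purity_ratio_per_triplet(self):
        calls = [_mk_call(5, 4, byproducts=1), _mk_call(6, 3, byproducts=1)]
        s = summarize(calls, CAG_CBE)
        assert s.purity_ratio == pytest.approx(11 / 2)

    def test_min_triplet_filter_and_empty_error(self):
        short = _mk_call(1, 2)  # 3 triplets < default 5
        with pytest.raises(ValueError, match="no aligned reads"):
            summarize([short], CAG_CBE)
        s = summarize([short], CAG_CBE, min_triplets=1)
        assert s.aligned_reads == 1

    def test_monotonicity_of_edited_fraction(self):
        base = [_mk_call(1, 9), _mk_call(0, 10)]
        s0 = summarize(base, CAG_CBE).edited_fraction
        s_edit = summarize(base + [_mk_call(3, 7)], CAG_CBE).edited_fraction
        s_pure = summarize(base + [_mk_call(0, 10)], CAG_CBE).edited_fraction
        assert s_edit >= s0 >= s_pure


@settings(deadline=None, max_examples=50)
@given(
    tracts=st.lists(
        st.lists(st.sampled_from(ALL_TRIPLETS), min_size=5, max_size=30),
        min_size=1,
        max_size=20,
    )
)
def test_summarize_matches_brute_force_recount(tracts):
    """Counts from the engine equal a naive recount of the same tracts."""
    spec = CAG_CBE
    calls = [
        call_read(f"r{i}", spec.left_flank + "".join(t) + spec.right_flank, spec)
        for i, t in enumerate(tracts)
    ]
    s = summarize(calls, spec, min_triplets=1)
    flat = [trip for t in tracts for trip in t]
    n_intended = sum(1 for t in flat if t in spec.intended)
    n_edited_reads = sum(1 for t in tracts if any(x in spec.intended for x in t))
    assert s.triplet_fraction_interrupted == pytest.approx(n_intended / len(flat))
    assert s.edited_reads == n_edited_reads
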