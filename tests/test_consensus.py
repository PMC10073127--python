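import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvburden.consensus import (
    AtomicRegion,
    CopyState,
    assign_copy_states,
    build_atomic_regions,
    filter_regions_by_repeats,
    merge_sample_calls,
    read_consensus_tsv,
    write_consensus_tsv,
)
from cnvburden.errors import UsageError
from cnvburden.intervals import GenomicInterval
from cnvburden.io_formats import CnvCall, EventType

iv = GenomicInterval


def call(caller, start, end, event=EventType.DEL, sample="s1", chrom="chr1"):
    return CnvCall(sample, caller, iv(chrom, start, end), event)


class TestMerge:
    def test_two_concordant_callers_merge(self):
        calls = [call("cnvnator", 100, 200), call("delly2", 110, 210)]
        (c,) = merge_sample_calls(calls)
        assert c.interval == iv("chr1", 100, 210)  # union span
        assert c.supporting_callers == {"cnvnator", "delly2"}
        assert c.support == 2

    def test_exactly_half_overlap_does_not_merge(self):
        # reciprocal overlap exactly 0.5: strict > 0.5 keeps them apart
        calls = [call("cnvnator", 0, 100), call("delly2", 50, 150)]
        assert merge_sample_calls(calls, min_support=1) == merge_sample_calls(
            [calls[0]], min_support=1
        ) + merge_sample_calls([calls[1]], min_support=1)

    def test_single_caller_support_floor(self):
        calls = [call("cnvnator", 100, 200)]
        assert merge_sample_calls(calls, min_support=2) == []
        (c,) = merge_sample_calls(calls, min_support=1)
        assert c.support == 1

    def test_transitive_chain_forms_one_component(self):
        # A-B and B-C overlap 0.6, A-C only 0.2: still one component
        calls = [
            call("cnvnator", 0, 100),
            call("delly2", 40, 140),
            call("lumpy", 80, 180),
        ]
        (c,) = merge_sample_calls(calls)
        assert c.interval == iv("chr1", 0, 180)
        assert c.support == 3

    def test_event_types_never_mix(self):
        calls = [
            call("cnvnator", 100, 200, EventType.DEL),
            call("delly2", 100, 200, EventType.DUP),
        ]
        out = merge_sample_calls(calls, min_support=1)
        assert len(out) == 2
        assert {c.event_type for c in out} == {EventType.DEL, EventType.DUP}

    def test_multiple_samples_rejected(self):
        with pytest.raises(UsageError):
            merge_sample_calls(
                [call("cnvnator", 0, 100, sample="s1"),
                 call("delly2", 0, 100, sample="s2")]
            )

    def test_min_support_monotonicity(self):
        calls = [
            call("cnvnator", 0, 100),
            call("delly2", 10, 110),
            call("lumpy", 500, 600),
        ]
        at2 = merge_sample_calls(calls, min_support=2)
        at1 = merge_sample_calls(calls, min_support=1)
        assert {c.interval for c in at2} <= {c.interval for c in at1}


calls_list_st = st.lists(
    st.builds(
        lambda caller, s, ln, et: call(caller, s, s + ln, et),
        st.sampled_from(["cnvnator", "gatk_gcnv", "delly2", "cnmops", "lumpy"]),
        st.integers(0, 2000),
        st.integers(50, 800),
        st.sampled_from(list(EventType)),
    ),
    max_size=12,
)


@given(calls_list_st, st.randoms(use_true_random=False))
def test_merge_is_order_invariant(calls, rnd):
    shuffled = list(calls)
    rnd.shuffle(shuffled)
    assert merge_sample_calls(calls, min_support=1) == merge_sample_calls(
        shuffled, min_support=1
    )


@given(calls_list_st)
def test_atomic_regions_partition_the_footprint(calls):
    consensus = merge_sample_calls(calls, min_support=1)
    regions = build_atomic_regions(consensus)
    # disjoint and sorted
    for a, b in zip(regions, regions[1:]):
        if a.interval.chrom == b.interval.chrom:
            assert a.interval.end <= b.interval.start
    # bp conservation: union of regions == union of consensus intervals
    def footprint(ivs):
        return {(i.chrom, p) for i in ivs for p in range(i.start, i.end)}

    assert footprint([r.interval for r in regions]) == footprint(
        [c.interval for c in consensus]
    )
    # every boundary coincides with a consensus endpoint
    endpoints = {p for c in consensus for p in (c.interval.start, c.interval.end)}
    for r in regions:
        assert r.interval.start in endpoints and r.interval.end in endpoints


class TestAtomicRegions:
    def test_overlapping_calls_split_at_boundaries(self):
        consensus = merge_sample_calls(
            [call("cnvnator", 100, 300)], min_support=1
        ) + merge_sample_calls(
            [call("cnvnator", 200, 400, sample="s2")], min_support=1
        )
        regions = build_atomic_regions(consensus)
        assert [r.interval for r in regions] == [
            iv("chr1", 100, 200), iv("chr1", 200, 300), iv("chr1", 300, 400)
        ]

    def test_single_call_single_region(self):
        consensus = merge_sample_calls([call("cnvnator", 100, 300)], min_support=1)
        (r,) = build_atomic_regions(consensus)
        assert r.interval == iv("chr1", 100, 300)

    def test_chromosomes_are_independent(self):
        consensus = merge_sample_calls(
            [call("cnvnator", 0, 100, chrom="chr1")], min_support=1
        ) + merge_sample_calls(
            [call("cnvnator", 0, 100, chrom="chr2", sample="s2")], min_support=1
        )
        regions = build_atomic_regions(consensus)
        assert {r.interval.chrom for r in regions} == {"chr1", "chr2"}


class TestRepeatFilter:
    def region(self, start, end):
        return AtomicRegion(f"chr1:{start}-{end}", iv("chr1", start, end))

    def test_half_covered_removed(self):
        regions = [self.region(0, 100)]
        assert filter_regions_by_repeats(regions, [iv("chr1", 0, 50)]) == []

    def test_just_under_half_retained(self):
        regions = [self.region(0, 100)]
        out = filter_regions_by_repeats(regions, [iv("chr1", 0, 49)])
        assert out == regions

    def test_overlapping_track_intervals_are_unioned(self):
        # [0,30) + [20,60) union to 60 bp of a 100 bp region -> removed
        regions = [self.region(0, 100)]
        track = [iv("chr1", 0, 30), iv("chr1", 20, 60)]
        assert filter_regions_by_repeats(regions, track) == []


class TestCopyStates:
    def _fixture(self):
        del_cons = merge_sample_calls(
            [call("cnvnator", 100, 400), call("delly2", 100, 400)]
        )
        both = merge_sample_calls(
            [call("cnvnator", 100, 400, sample="s3"),
             call("delly2", 100, 400, sample="s3"),
             call("cnvnator", 100, 400, EventType.DUP, sample="s3"),
             call("delly2", 100, 400, EventType.DUP, sample="s3")]
        )
        consensus = del_cons + both
        regions = build_atomic_regions(consensus)
        return consensus, regions

    def test_states_and_conflict(self):
        consensus, regions = self._fixture()
        matrix = assign_copy_states(regions, consensus, ["s1", "s2", "s3"])
        rid = regions[0].region_id
        assert matrix.state(rid, "s1") is CopyState.LOSS
        assert matrix.state(rid, "s2") is CopyState.NEUTRAL
        assert matrix.state(rid, "s3") is CopyState.CONFLICT

    def test_region_inside_wider_consensus(self):
        consensus = merge_sample_calls(
            [call("cnvnator", 100, 400), call("delly2", 100, 400)]
        )
        region = AtomicRegion("chr1:200-300", iv("chr1", 200, 300))
        matrix = assign_copy_states([region], consensus, ["s1"])
        assert matrix.state("chr1:200-300", "s1") is CopyState.LOSS

    def test_straddling_region_is_a_consistency_error(self):
        consensus = merge_sample_calls(
            [call("cnvnator", 100, 400), call("delly2", 100, 400)]
        )
        foreign = AtomicRegion("chr1:50-150", iv("chr1", 50, 150))
        from cnvburden.errors import ValidationError

        with pytest.raises(ValidationError, match="straddles"):
            assign_copy_states([foreign], consensus, ["s1"])

    def test_grid_is_complete(self):
        consensus, regions = self._fixture()
        matrix = assign_copy_states(regions, consensus, ["s1", "s2", "s3"])
        assert matrix.states.shape == (len(regions), 3)
        assert np.all(matrix.states >= 0)


def test_consensus_tsv_round_trip(tmp_path):
    consensus = merge_sample_calls(
        [call("cnvnator", 100, 200), call("delly2", 110, 210)]
    )
    p = tmp_path / "cons.tsv"
    write_consensus_tsv(consensus, p)
    back = read_consensus_tsv(p)
    assert len(back) == 1
    assert back[0].interval == consensus[0].interval
    assert back[0].supporting_callers == consensus[0].supporting_callers
    assert back[0].sample_id == consensus[0].sample_id
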