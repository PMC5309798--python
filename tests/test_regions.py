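import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosagescope.core_io import GenomeBuild
from dosagescope.regions import (
    CoverageProfile,
    Scope,
    coverage_profile,
    find_peak_regions,
    genome_fraction,
    merge_cnvrs,
    region_overlap,
    union_intervals,
)

from conftest import make_cnv, random_cnv_set
from oracles import per_base_overlap, per_base_peaks, per_base_segments


class TestMergeCnvrs:
    def test_partial_overlap_merges(self):
        regs = merge_cnvrs([make_cnv(100, 200), make_cnv(150, 300)])
        assert len(regs) == 1
        assert regs[0].interval == (100, 300)
        assert len(regs[0].members) == 2

    def test_disjoint_stay_separate(self):
        regs = merge_cnvrs([make_cnv(100, 200), make_cnv(300, 400)])
        assert len(regs) == 2

    def test_bookended_cnvs_merge(self):
        regs = merge_cnvrs([make_cnv(100, 200), make_cnv(200, 300)])
        assert len(regs) == 1
        assert regs[0].interval == (100, 300)

    def test_typed_scope_filters_other_type(self):
        gain = make_cnv(100, 200, cnv_type="gain")
        loss = make_cnv(150, 300, cnv_type="loss")
        regs = merge_cnvrs([gain, loss], Scope.GAIN_ONLY)
        # oracle: filter to gains, then union by endpoint sweep
        assert len(regs) == 1
        assert regs[0].interval == (100, 200)
        assert regs[0].member_ids == (gain.id,)

    def test_mixed_interpretations_rejected(self):
        with pytest.raises(ValueError, match="interpretation"):
            merge_cnvrs([make_cnv(0, 100, interpretation="benign"),
                         make_cnv(50, 200, interpretation="pathogenic")])

    def test_partition_and_order_invariance(self, toy_build):
        rng = np.random.default_rng(21)
        cnvs = random_cnv_set(rng, 80, toy_build)
        regs = merge_cnvrs(cnvs, Scope.GROUPED)
        # every CNV is in exactly one CNVR
        assignment = {m.id: r.region_id for r in regs for m in r.members}
        assert sorted(assignment) == sorted(c.id for c in cnvs)
        # region span equals the union of member intervals
        for r in regs:
            (lo, hi), = union_intervals([m.interval for m in r.members])
            assert (lo, hi) == r.interval
        # shuffling the input changes nothing
        shuffled = list(cnvs)
        rng.shuffle(shuffled)
        regs2 = merge_cnvrs(shuffled, Scope.GROUPED)
        assert [(r.interval, sorted(r.member_ids)) for r in regs] == [
            (r.interval, sorted(r.member_ids)) for r in regs2
        ]


class TestCoverageProfile:
    def test_two_overlapping_members(self):
        region = merge_cnvrs([make_cnv(100, 200), make_cnv(150, 300)])[0]
        prof = coverage_profile(region)
        assert prof.segments == ((100, 150, 1), (150, 200, 2), (200, 300, 1))

    def test_single_member(self):
        region = merge_cnvrs([make_cnv(0, 50)])[0]
        assert coverage_profile(region).segments == ((0, 50, 1),)

    def test_three_identical_members(self):
        cnvs = [make_cnv(100, 400, cid=f"c{i}") for i in range(3)]
        region = merge_cnvrs(cnvs)[0]
        assert coverage_profile(region).segments == ((100, 400, 3),)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_per_base_oracle_and_conserves_mass(self, data):
        n = data.draw(st.integers(1, 8))
        intervals = []
        for _ in range(n):
            start = data.draw(st.integers(0, 400))
            length = data.draw(st.integers(50, 200))
            intervals.append((start, start + length))
        # keep them overlap-connected by chaining onto the running union
        intervals = _connect(intervals)
        cnvs = [make_cnv(s, e, cid=f"c{i}") for i, (s, e) in enumerate(intervals)]
        region = merge_cnvrs(cnvs)[0]
        prof = coverage_profile(region)
        lo, hi = region.interval
        assert list(prof.segments) == per_base_segments(intervals, lo, hi)
        mass = sum((e - s) * d for s, e, d in prof.segments)
        assert mass == sum(e - s for s, e in intervals)


def _connect(intervals):
    """Shift intervals so they form a single overlap-connected component."""
    out = [intervals[0]]
    for start, end in intervals[1:]:
        hi = max(e for _, e in out)
        lo = min(s for s, _ in out)
        length = end - start
        anchor = lo + (start % max(1, hi - lo + length))
        s = max(0, min(anchor, hi))  # touches or overlaps the union so far
        out.append((s, s + length))
    return out


class TestFindPeakRegions:
    def test_single_cnv_region_entire_cnv_is_peak(self):
        # one-CNV regions keep the whole CNV as their depth-1 peak
        region = merge_cnvrs([make_cnv(500, 900)])[0]
        (peak,) = find_peak_regions(coverage_profile(region))
        assert peak.interval == (500, 900)
        assert peak.depth == 1

    def test_two_local_maxima(self):
        # depth sequence 1,2,1,3,1 -> the depth-2 and depth-3 plateaus
        prof = CoverageProfile(
            "r", "1",
            ((0, 100, 1), (100, 200, 2), (200, 300, 1), (300, 400, 3), (400, 500, 1)),
        )
        peaks = find_peak_regions(prof)
        assert [(p.start, p.end, p.depth) for p in peaks] == [
            (100, 200, 2), (300, 400, 3)
        ]

    def test_monotone_rise_and_fall_single_peak(self):
        prof = CoverageProfile(
            "r", "1",
            ((0, 100, 1), (100, 200, 2), (200, 300, 3), (300, 400, 2), (400, 500, 1)),
        )
        peaks = find_peak_regions(prof)
        assert [(p.start, p.end, p.depth) for p in peaks] == [(200, 300, 3)]

    def test_edge_plateau_qualifies_against_zero_flank(self):
        # depth falls 3,2,1 from the CNVR start: the leading plateau is a peak
        prof = CoverageProfile("r", "1", ((0, 100, 3), (100, 200, 2), (200, 300, 1)))
        peaks = find_peak_regions(prof)
        assert [(p.start, p.end, p.depth) for p in peaks] == [(0, 100, 3)]

    def test_agrees_with_per_base_oracle_on_random_profiles(self, toy_build):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 10))
            intervals = []
            cursor = int(rng.integers(0, 100))
            for _ in range(n):
                start = max(0, cursor + int(rng.integers(-150, 80)))
                length = int(rng.integers(50, 300))
                intervals.append((start, start + length))
                cursor = start + length
            intervals = _connect(intervals)
            cnvs = [make_cnv(s, e, cid=f"c{i}") for i, (s, e) in enumerate(intervals)]
            for region in merge_cnvrs(cnvs):
                prof = coverage_profile(region)
                got = [(p.start, p.end, p.depth) for p in find_peak_regions(prof)]
                assert got == per_base_peaks(
                    [m.interval for m in region.members], *region.interval
                )

    def test_peaks_disjoint_nested_and_nonempty(self, toy_build):
        rng = np.random.default_rng(9)
        cnvs = random_cnv_set(rng, 120, toy_build)
        for region in merge_cnvrs(cnvs):
            peaks = find_peak_regions(coverage_profile(region))
            assert peaks, "every CNVR must contain at least one peak"
            spans = sorted(p.interval for p in peaks)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2, "peaks must be disjoint"
            for p in peaks:
                assert region.start <= p.start < p.end <= region.end


class TestGenomeFraction:
    def test_whole_single_chromosome(self):
        build = GenomeBuild("t", {"1": 100})
        assert genome_fraction([("1", 0, 100)], build) == 1.0

    def test_empty_set(self):
        build = GenomeBuild("t", {"1": 100})
        assert genome_fraction([], build) == 0.0

    def test_quarter(self):
        build = GenomeBuild("t", {"1": 100})
        assert genome_fraction([("1", 0, 25)], build) == 0.25

    def test_interval_beyond_end_errors(self):
        build = GenomeBuild("t", {"1": 100})
        with pytest.raises(ValueError, match="beyond"):
            genome_fraction([("1", 50, 150)], build)

    def test_overlapping_intervals_unioned_first(self):
        build = GenomeBuild("t", {"1": 100, "2": 100})
        assert genome_fraction([("1", 0, 30), ("1", 20, 50)], build) == 0.25


class TestRegionOverlap:
    def test_half_overlap(self):
        bp, frac = region_overlap([("1", 0, 100)], [("1", 50, 150)])
        assert (bp, frac) == (50, 0.5)

    def test_identical_sets(self):
        ivs = [("1", 10, 60), ("2", 0, 40)]
        bp, frac = region_overlap(ivs, ivs)
        assert frac == 1.0

    def test_split_a_against_spanning_b(self):
        bp, frac = region_overlap(
            [("1", 0, 10), ("1", 20, 30)], [("1", 5, 25)]
        )
        assert (bp, frac) == (10, 0.5)

    def test_empty_a_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            region_overlap([], [("1", 0, 10)])

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 900, 6), rng.integers(1, 120, 6))]
            b = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 900, 6), rng.integers(1, 120, 6))]
            bp, _ = region_overlap(
                [("1", s, e) for s, e in a], [("1", s, e) for s, e in b]
            )
            assert bp == per_base_overlap(a, b, 0, 1100)
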