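from collections import Counter

import numpy as np
import pytest

from csmfinder.asm_am import AMLocus
from csmfinder.io import GenomicInterval, ReadPattern
from csmfinder.regions import (
    build_control_regions,
    build_region_cell_data,
    coverage_filter,
    extend_and_merge,
    find_bipolar_seeds,
)
from csmfinder.segments import Segment4CpG


def seg(positions, per_cell, chrom="chr1"):
    return Segment4CpG(
        chrom, tuple(positions), {c: Counter(t) for c, t in per_cell.items()}
    )


class TestBipolarSeeds:
    def test_cross_cell_bipolar_segment_is_seed(self):
        s = seg([0, 10, 20, 30], {"c1": {"1111": 2}, "c2": {"0000": 1}})
        assert find_bipolar_seeds([s], []) == [s]

    def test_within_cell_bipolarity_alone_is_not_seed(self):
        s = seg([0, 10, 20, 30], {"c1": {"1111": 1, "0000": 1}})
        assert find_bipolar_seeds([s], []) == []

    def test_am_locus_excluded_even_if_bipolar(self):
        s = seg([0, 10, 20, 30], {"c1": {"1111": 2}, "c2": {"0000": 1}})
        am = [AMLocus("chr1", (0, 10, 20, 30), "hairpin")]
        assert find_bipolar_seeds([s], am) == []

    def test_incomplete_patterns_are_not_seeds(self):
        s = seg([0, 10, 20, 30], {"c1": {"1110": 3}, "c2": {"0000": 3}})
        assert find_bipolar_seeds([s], []) == []

    def test_two_cells_each_with_both_patterns_is_seed(self):
        # a different fully-unmethylated cell exists for each fully-
        # methylated one, so the cross-cell requirement holds
        s = seg(
            [0, 10, 20, 30],
            {"c1": {"1111": 1, "0000": 1}, "c2": {"1111": 1, "0000": 1}},
        )
        assert find_bipolar_seeds([s], []) == [s]


class TestExtendAndMerge:
    def test_flank_extension(self):
        s = seg([1000, 1040, 1070, 1100], {"a": {"1111": 1}})
        (region,) = extend_and_merge([s], [s], flank=100)
        assert (region.interval.start, region.interval.end) == (900, 1201)

    def test_overlapping_extended_spans_merge_and_stay_seeded(self):
        a = seg([1000, 1040, 1070, 1100], {"a": {"1111": 1}, "b": {"0000": 1}})
        b = seg([1250, 1260, 1270, 1299], {"a": {"1010": 1}})
        (region,) = extend_and_merge([a], [a, b], flank=100)
        assert (region.interval.start, region.interval.end) == (900, 1400)
        assert region.seed_count == 1
        assert len(region.member_segments) == 2

    def test_distant_seeds_stay_separate(self):
        a = seg([1000, 1010, 1020, 1030], {"a": {"1111": 1}, "b": {"0000": 1}})
        b = seg([2400, 2410, 2420, 2430], {"a": {"1111": 1}, "b": {"0000": 1}})
        regions = extend_and_merge([a, b], [a, b], flank=100)
        assert len(regions) == 2

    def test_unseeded_regions_dropped_unless_control_universe(self):
        a = seg([1000, 1010, 1020, 1030], {"a": {"1111": 1}, "b": {"0000": 1}})
        b = seg([5000, 5010, 5020, 5030], {"a": {"1010": 1}})
        assert len(extend_and_merge([a], [a, b], flank=100)) == 1
        assert len(extend_and_merge([a], [a, b], flank=100, require_seed=False)) == 2

    def test_flank_zero_nonoverlapping_identity_limit(self):
        segs = [
            seg([100, 110, 120, 130], {"a": {"1111": 1}}),
            seg([500, 510, 520, 530], {"a": {"1111": 1}}),
        ]
        regions = extend_and_merge(segs, segs, flank=0, require_seed=False)
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (100, 131),
            (500, 531),
        ]

    def test_merge_is_order_independent(self):
        rng = np.random.default_rng(1)
        segs = [
            seg(sorted(int(p) + np.array([0, 5, 9, 14])), {"a": {"1111": 1}})
            for p in rng.integers(0, 2000, size=40)
        ]
        fwd = extend_and_merge(segs, segs, flank=50, require_seed=False)
        rev = extend_and_merge(segs[::-1], segs[::-1], flank=50, require_seed=False)
        assert [r.interval for r in fwd] == [r.interval for r in rev]

    def test_matches_brute_force_union_oracle(self):
        # naive O(n^2) interval union over extended spans
        rng = np.random.default_rng(7)
        for _ in range(50):
            starts = rng.integers(0, 3000, size=rng.integers(1, 25))
            segs = [
                seg([int(s), int(s) + 7, int(s) + 15, int(s) + 21], {"a": {"1111": 1}})
                for s in starts
            ]
            flank = int(rng.integers(0, 150))
            spans = [
                (max(0, s.span[0] - flank), s.span[1] + flank) for s in segs
            ]
            merged_oracle = []
            for span in sorted(spans):
                placed = False
                for i, m in enumerate(merged_oracle):
                    if span[0] < m[1] and m[0] < span[1]:
                        merged_oracle[i] = (min(m[0], span[0]), max(m[1], span[1]))
                        placed = True
                        break
                if not placed:
                    merged_oracle.append(span)
            # a second pass resolves chains created by later extensions
            changed = True
            while changed:
                changed = False
                out = []
                for span in sorted(merged_oracle):
                    if out and span[0] < out[-1][1]:
                        out[-1] = (out[-1][0], max(out[-1][1], span[1]))
                        changed = True
                    else:
                        out.append(span)
                merged_oracle = out
            got = extend_and_merge(segs, segs, flank=flank, require_seed=False)
            assert [(r.interval.start, r.interval.end) for r in got] == merged_oracle


def region_with_cell_totals(totals, region=None):
    """Build one merged-region + counts with the given per-cell totals."""
    region = region or GenomicInterval("chr1", 0, 200)
    reads = []
    for ci, total in enumerate(totals):
        # one site per count unit at distinct positions, all unmethylated
        for k in range(total):
            reads.append(
                ReadPattern(f"c{ci}", "chr1", (k,), (0,))
            )
    from csmfinder.regions import MergedRegion

    merged = [MergedRegion(region, [], 1)]
    data = build_region_cell_data(merged, reads)
    return merged, data


class TestCoverageFilter:
    def test_five_cells_at_threshold_kept(self):
        merged, data = region_with_cell_totals([12, 11, 10, 10, 10])
        (cand,) = coverage_filter(merged, data, min_cells=5, min_counts=10)
        assert cand.n_cells == 5

    def test_four_covering_cells_dropped(self):
        merged, data = region_with_cell_totals([12, 11, 10, 10, 9])
        assert coverage_filter(merged, data, min_cells=5, min_counts=10) == []

    def test_exactly_min_counts_is_covering(self):
        merged, data = region_with_cell_totals([10, 10, 10, 10, 10])
        (cand,) = coverage_filter(merged, data, min_cells=5, min_counts=10)
        assert all(d.total_sum == 10 for d in cand.per_cell.values())

    def test_non_covering_cells_dropped_from_kept_region(self):
        merged, data = region_with_cell_totals([12, 11, 10, 10, 10, 3])
        (cand,) = coverage_filter(merged, data, min_cells=5, min_counts=10)
        assert "c5" not in cand.per_cell


class TestRegionCellData:
    def test_counts_rebuilt_from_all_overlapping_reads(self):
        # a 2-CpG read contributes to the region even though it cannot
        # form a 4-CpG segment
        from csmfinder.regions import MergedRegion

        region = MergedRegion(GenomicInterval("chr1", 0, 100), [], 1)
        reads = [
            ReadPattern("a", "chr1", (10, 20), (1, 0)),
            ReadPattern("a", "chr1", (10, 20, 30, 40), (1, 1, 1, 1)),
            ReadPattern("a", "chr1", (150, 160), (1, 1)),  # outside
        ]
        data = build_region_cell_data([region], reads)
        sites = {s.position: (s.meth, s.total) for s in data["chr1:0-100"]["a"].sites}
        assert sites == {10: (2, 2), 20: (1, 2), 30: (1, 1), 40: (1, 1)}


class TestControls:
    def test_candidates_are_contained_in_control_universe(self):
        rng = np.random.default_rng(9)
        reads = []
        for ci in range(6):
            for start in rng.integers(0, 5000, size=30):
                start = int(start)
                pattern = "1111" if ci < 3 else "0000"
                reads.append(
                    ReadPattern(
                        f"c{ci}",
                        "chr1",
                        (start, start + 7, start + 15, start + 21),
                        tuple(int(c) for c in pattern),
                    )
                )
        from csmfinder.segments import extract_4cpg_segments

        segs = extract_4cpg_segments(reads)
        seeds = find_bipolar_seeds(segs, [])
        merged = extend_and_merge(seeds, segs, flank=100)
        data = build_region_cell_data(merged, reads)
        candidates = coverage_filter(merged, data, min_cells=2, min_counts=4)
        controls = build_control_regions(
            segs, reads, flank=100, min_cells=2, min_counts=4
        )
        for cand in candidates:
            assert any(
                ctl.interval.start <= cand.interval.start
                and cand.interval.end <= ctl.interval.end
                for ctl in controls
            )

    def test_empty_segments_give_empty_controls(self):
        assert build_control_regions([], []) == []
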