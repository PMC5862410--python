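"""Candidate CSM region construction.

Three steps: (1) bipolar seeds — ASM-filtered 4-CpG segments fully
methylated in at least one cell and fully unmethylated in a *different*
cell, excluding AM loci; (2) seeds and all other ASM-filtered segments
extended by a 100 bp flank and transitively merged, keeping merged
intervals that contain at least one seed; (3) coverage filter — a region
is kept iff at least ``min_cells`` cells each contribute at least
``min_counts`` cytosine observations inside it.  Running the same
extend/merge/filter over all ASM-filtered segments without the seed
requirement yields the matched control set.

Site-level counts (m_jri, n_jri) are rebuilt from *all* reads
overlapping a merged region, not only the 4-CpG-segment reads, since the
downstream beta-binomial layer operates on per-CpG counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .asm_am import FULL_METH, FULL_UNMETH, AMLocus
from .io import GenomicInterval, ReadPattern, RegionCellData, SiteCount
from .segments import Segment4CpG, SegmentKey


@dataclass
class MergedRegion:
    """A flank-extended union of segment spans, with seed provenance."""

    interval: GenomicInterval
    member_segments: list[SegmentKey] = field(default_factory=list)
    seed_count: int = 0


@dataclass
class CandidateRegion:
    """A merged region passing the coverage filter, with per-cell counts."""

    interval: GenomicInterval
    seed_count: int
    member_segments: list[SegmentKey]
    per_cell: dict[str, RegionCellData]

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    @property
    def n_cells(self) -> int:
        return len(self.per_cell)


def find_bipolar_seeds(
    segments_after_asm: Sequence[Segment4CpG], am_loci: Iterable[AMLocus]
) -> list[Segment4CpG]:
    """Bipolar segments (cross-cell 1111/0000) that are not AM loci."""
    am_keys = {locus.key for locus in am_loci}
    seeds = []
    for seg in segments_after_asm:
        if seg.key in am_keys:
            continue
        meth_cells = {
            c for c, tally in seg.per_cell.items() if tally.get(FULL_METH, 0) > 0
        }
        unmeth_cells = {
            c for c, tally in seg.per_cell.items() if tally.get(FULL_UNMETH, 0) > 0
        }
        # at least one fully-methylated cell and a *different* fully-unmethylated
        # one; a single cell carrying both patterns alone is AM, not bipolar
        if meth_cells and unmeth_cells and len(meth_cells | unmeth_cells) >= 2:
            seeds.append(seg)
    return seeds


def extend_and_merge(
    seeds: Sequence[Segment4CpG],
    all_segments_after_asm: Sequence[Segment4CpG],
    flank: int = 100,
    require_seed: bool = True,
) -> list[MergedRegion]:
    """Extend segment spans by ``flank`` bp and union transitive overlaps.

    Every segment span [pos1, pos4+1) is widened on both sides; strictly
    overlapping widened intervals merge into one.  With
    ``require_seed=True`` only merged intervals containing >=1 seed are
    returned (candidates); with ``require_seed=False`` all merged
    intervals are returned (the control universe).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seed_keys = {seg.key for seg in seeds}
    by_key: dict[SegmentKey, Segment4CpG] = {s.key: s for s in all_segments_after_asm}
    for seg in seeds:  # seeds are segments too, even if caller passed them separately
        by_key.setdefault(seg.key, seg)

    by_chrom: dict[str, list[Segment4CpG]] = defaultdict(list)
    for seg in by_key.values():
        by_chrom[seg.chrom].append(seg)

    merged: list[MergedRegion] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.span)
        current: MergedRegion | None = None
        cur_start = cur_end = 0
        for seg in segs:
            start = max(0, seg.span[0] - flank)
            end = seg.span[1] + flank
            if current is not None and start < cur_end:
                cur_end = max(cur_end, end)
                current.member_segments.append(seg.key)
                current.seed_count += seg.key in seed_keys
            else:
                if current is not None:
                    current.interval = GenomicInterval(chrom, cur_start, cur_end)
                    merged.append(current)
                current = MergedRegion(
                    GenomicInterval(chrom, start, end),
                    [seg.key],
                    int(seg.key in seed_keys),
                )
                cur_start, cur_end = start, end
        if current is not None:
            current.interval = GenomicInterval(chrom, cur_start, cur_end)
            merged.append(current)
    if require_seed:
        merged = [r for r in merged if r.seed_count >= 1]
    return merged


def build_region_cell_data(
    regions: Sequence[MergedRegion], reads: Sequence[ReadPattern]
) -> dict[str, dict[str, RegionCellData]]:
    """Aggregate site-level counts per region per cell from all reads.

    Returns ``{region_id: {cell_id: RegionCellData}}``.  Both strands of
    a dyad pool because positions are normalized on input.
    """
    by_chrom: dict[str, list[MergedRegion]] = defaultdict(list)
    for region in regions:
        by_chrom[region.interval.chrom].append(region)
    for chrom_regions in by_chrom.values():
        chrom_regions.sort(key=lambda r: (r.interval.start, r.interval.end))

    # accumulate counts: region -> cell -> position -> [meth, total]
    acc: dict[int, dict[str, dict[int, list[int]]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(lambda: [0, 0]))
    )
    region_index = {id(r): r for rs in by_chrom.values() for r in rs}
    for read in reads:
        chrom_regions = by_chrom.get(read.chrom)
        if not chrom_regions:
            continue
        for region in chrom_regions:  # regions per chrom are few and disjoint
            iv = region.interval
            if read.cpg_positions[-1] < iv.start:
                continue
            if read.cpg_positions[0] >= iv.end:
                continue
            for pos, state in zip(read.cpg_positions, read.states):
                if iv.start <= pos < iv.end:
                    cell_acc = acc[id(region)][read.cell_id][pos]
                    cell_acc[0] += state
                    cell_acc[1] += 1

    out: dict[str, dict[str, RegionCellData]] = {}
    for rid, cells in acc.items():
        region = region_index[rid]
        iv = region.interval
        region_id = f"{iv.chrom}:{iv.start}-{iv.end}"
        out[region_id] = {}
        # sorted cells keep float accumulation independent of read order
        for cell_id, positions in sorted(cells.items()):
            sites = [
                SiteCount(pos, meth, total)
                for pos, (meth, total) in sorted(positions.items())
            ]
            out[region_id][cell_id] = RegionCellData(iv, cell_id, sites)
    return out


def coverage_filter(
    regions: Sequence[MergedRegion],
    region_cell_data: dict[str, dict[str, RegionCellData]],
    min_cells: int = 5,
    min_counts: int = 10,
) -> list[CandidateRegion]:
    """Keep regions covered by >= ``min_cells`` cells with >= ``min_counts``
    cytosine observations each; non-covering cells are dropped."""
    out = []
    for region in regions:
        iv = region.interval
        region_id = f"{iv.chrom}:{iv.start}-{iv.end}"
        cells = region_cell_data.get(region_id, {})
        covering = {
            cell_id: data
            for cell_id, data in cells.items()
            if data.total_sum >= min_counts
        }
        if len(covering) >= min_cells:
            out.append(
                CandidateRegion(
                    iv, region.seed_count, list(region.member_segments), covering
                )
            )
    return sorted(out, key=lambda r: (r.interval.chrom, r.interval.start))


def build_control_regions(
    all_segments_after_asm: Sequence[Segment4CpG],
    reads: Sequence[ReadPattern],
    flank: int = 100,
    min_cells: int = 5,
    min_counts: int = 10,
) -> list[CandidateRegion]:
    """The control set: same extend/merge/coverage machinery, no seed needed."""
    merged = extend_and_merge(
        [], all_segments_after_asm, flank=flank, require_seed=False
    )
    data = build_region_cell_data(merged, reads)
    return coverage_filter(merged, data, min_cells=min_cells, min_counts=min_counts)


def write_candidate_regions(
    bed_path: str | Path, counts_path: str | Path, regions: Sequence[CandidateRegion]
) -> None:
    """Candidate/control BED + per-cell count TSV
    (region_id, cell_id, position, meth, total)."""
    with open(bed_path, "w") as fh:
        for region in regions:
            iv = region.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{region.seed_count}\n")
    with open(counts_path, "w") as fh:
        fh.write("region_id\tcell_id\tposition\tmeth\ttotal\n")
        for region in regions:
            for cell_id in sorted(region.per_cell):
                for site in region.per_cell[cell_id].sites:
                    fh.write(
                        f"{region.region_id}\t{cell_id}\t{site.position}"
                        f"\t{site.meth}\t{site.total}\n"
                    )
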