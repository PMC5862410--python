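"""Within-cell methylation variation: ASM exclusion and AM detection.

Allele-specific methylation (ASM) loci come from external annotation
(imprinted loci mapped in reciprocal mouse crosses) and are excluded by
position membership.  Asymmetric methylation (AM) — a molecule
methylated on one strand but not its complement — is detected from
hairpin bisulfite read pairs (one strand "1111", its mate "0000" over
the same 4-CpG window) and, as a proxy in single-cell data, from a cell
carrying both a fully methylated and a fully unmethylated read at one
segment.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io import GenomicInterval, ReadPattern
from .segments import Segment4CpG, SegmentKey

FULL_METH = "1111"
FULL_UNMETH = "0000"


@dataclass(frozen=True)
class AMLocus:
    """An asymmetrically methylated 4-CpG segment with its evidence source."""

    chrom: str
    cpg_positions: tuple[int, int, int, int]
    evidence: str  # {hairpin, single_cell, both}

    def __post_init__(self) -> None:
        if self.evidence not in ("hairpin", "single_cell", "both"):
            raise ValueError(f"bad evidence {self.evidence!r}")

    @property
    def key(self) -> SegmentKey:
        return (self.chrom, self.cpg_positions)


def _interval_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end)
    return trees


def filter_asm(
    segments: Sequence[Segment4CpG], asm_loci: Iterable[GenomicInterval]
) -> tuple[list[Segment4CpG], list[Segment4CpG]]:
    """Partition segments into (kept, removed) by ASM overlap.

    A segment is removed iff any of its four CpG positions lies inside
    any ASM interval (position membership, not span overlap: the ASM
    annotation is CpG-resolved).
    """
    trees = _interval_trees(asm_loci)
    kept: list[Segment4CpG] = []
    removed: list[Segment4CpG] = []
    for seg in segments:
        tree = trees.get(seg.chrom)
        if tree is not None and any(tree.overlaps_point(p) for p in seg.cpg_positions):
            removed.append(seg)
        else:
            kept.append(seg)
    return kept, removed


def detect_am_hairpin(hairpin_reads: Sequence[ReadPattern]) -> list[AMLocus]:
    """AM loci from hairpin read pairs.

    Pairs are linked by ``pair_id``; the two mates carry complementary
    strands over identical (normalized) CpG coordinates.  A 4-CpG window
    is AM iff at least one pair shows "1111" on one strand and "0000" on
    the other over the same coordinates; partial-overlap windows are
    ignored.  Unpaired reads are skipped with a warning.
    """
    by_pair: dict[str, list[ReadPattern]] = defaultdict(list)
    n_unpaired = 0
    for read in hairpin_reads:
        if read.pair_id is None:
            n_unpaired += 1
            continue
        by_pair[read.pair_id].append(read)

    am: dict[SegmentKey, None] = {}
    for pair_id, mates in by_pair.items():
        plus = [r for r in mates if r.strand == "+"]
        minus = [r for r in mates if r.strand == "-"]
        if not plus or not minus:
            n_unpaired += len(mates)
            continue
        for a in plus:
            for b in minus:
                if a.chrom != b.chrom:
                    continue
                wa = _windows(a)
                wb = _windows(b)
                for quad in set(wa) & set(wb):
                    pa, pb = wa[quad], wb[quad]
                    if {pa, pb} == {FULL_METH, FULL_UNMETH}:
                        am[(a.chrom, quad)] = None
    if n_unpaired:
        warnings.warn(
            f"{n_unpaired} hairpin read(s) without a mate skipped", stacklevel=2
        )
    return [
        AMLocus(chrom, quad, "hairpin") for chrom, quad in sorted(am)
    ]


def _windows(read: ReadPattern) -> dict[tuple[int, int, int, int], str]:
    out = {}
    for i in range(len(read.cpg_positions) - 3):
        quad = read.cpg_positions[i : i + 4]
        out[quad] = "".join(str(s) for s in read.states[i : i + 4])
    return out


def detect_am_single_cell(segments: Sequence[Segment4CpG]) -> list[AMLocus]:
    """AM loci from single-cell tallies.

    A segment is AM iff some single cell carries both a fully methylated
    and a fully unmethylated read (within-cell bipolarity).  Bipolarity
    across *different* cells is a CSM seed, not AM.
    """
    out = []
    for seg in segments:
        for tally in seg.per_cell.values():
            if tally.get(FULL_METH, 0) > 0 and tally.get(FULL_UNMETH, 0) > 0:
                out.append(AMLocus(seg.chrom, seg.cpg_positions, "single_cell"))
                break
    return sorted(out, key=lambda locus: locus.key)


def merge_am(
    hairpin_set: Iterable[AMLocus], sc_set: Iterable[AMLocus]
) -> list[AMLocus]:
    """Union of hairpin and single-cell AM calls, evidence recorded."""
    table: dict[SegmentKey, str] = {}
    for locus in hairpin_set:
        table[locus.key] = "hairpin"
    for locus in sc_set:
        table[locus.key] = "both" if locus.key in table else "single_cell"
    return [
        AMLocus(chrom, quad, table[(chrom, quad)]) for chrom, quad in sorted(table)
    ]


def write_am_loci(path: str | Path, loci: Sequence[AMLocus]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos1\tpos2\tpos3\tpos4\tevidence\n")
        for locus in sorted(loci, key=lambda am: am.key):
            p = locus.cpg_positions
            fh.write(f"{locus.chrom}\t{p[0]}\t{p[1]}\t{p[2]}\t{p[3]}\t{locus.evidence}\n")
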