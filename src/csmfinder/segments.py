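"""4-CpG segment extraction and per-cell pattern tallies.

A 4-CpG segment is a window of four consecutive CpG sites observed on a
single sequencing read; it is the unit at which methylation patterns
(e.g. fully methylated "1111" vs fully unmethylated "0000") are tallied
per cell.  A read covering c CpGs contributes all max(0, c-3) sliding
windows; identical position quadruples across reads and cells collapse
into one segment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import ReadPattern

SegmentKey = tuple[str, tuple[int, int, int, int]]


@dataclass
class Segment4CpG:
    """A 4-CpG window with per-cell read-pattern tallies."""

    chrom: str
    cpg_positions: tuple[int, int, int, int]
    per_cell: dict[str, Counter] = field(default_factory=dict)

    @property
    def key(self) -> SegmentKey:
        return (self.chrom, self.cpg_positions)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [pos1, pos4+1), 0-based half-open."""
        return (self.cpg_positions[0], self.cpg_positions[3] + 1)

    @property
    def n_cells(self) -> int:
        return len(self.per_cell)

    @property
    def total_reads(self) -> int:
        return sum(sum(c.values()) for c in self.per_cell.values())

    def cell_has_pattern(self, cell_id: str, pattern: str) -> bool:
        return self.per_cell.get(cell_id, Counter()).get(pattern, 0) > 0


def extract_4cpg_segments(
    reads: Iterable[ReadPattern], max_span: int | None = None
) -> list[Segment4CpG]:
    """Extract all sliding 4-CpG windows from read-level calls.

    ``max_span`` optionally caps the genomic distance pos4-pos1 of a
    window (default unlimited: "neighboring" means consecutive within
    the read).  Returns segments sorted by (chrom, positions).
    """
    table: dict[SegmentKey, Segment4CpG] = {}
    for read in reads:
        pos, states = read.cpg_positions, read.states
        for i in range(len(pos) - 3):
            quad = pos[i : i + 4]
            if max_span is not None and quad[3] - quad[0] > max_span:
                continue
            key = (read.chrom, quad)
            seg = table.get(key)
            if seg is None:
                seg = Segment4CpG(read.chrom, quad)
                table[key] = seg
            pattern = "".join(str(s) for s in states[i : i + 4])
            seg.per_cell.setdefault(read.cell_id, Counter())[pattern] += 1
    return [table[k] for k in sorted(table)]


def merge_segment_tallies(
    a: Sequence[Segment4CpG], b: Sequence[Segment4CpG]
) -> list[Segment4CpG]:
    """Merge two segment sets by key, summing per-cell pattern tallies."""
    table: dict[SegmentKey, Segment4CpG] = {}
    for seg in list(a) + list(b):
        out = table.get(seg.key)
        if out is None:
            out = Segment4CpG(seg.chrom, seg.cpg_positions)
            table[seg.key] = out
        for cell, tally in seg.per_cell.items():
            out.per_cell.setdefault(cell, Counter()).update(tally)
    return [table[k] for k in sorted(table)]


def segment_summary(
    segments: Sequence[Segment4CpG],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise segments and cells.

    Returns ``(per_segment, per_cell)``: per segment the number of
    covering cells and mean read depth (total reads / covering cells);
    per cell the number of segments observed.  Deterministic ordering.
    """
    seg_rows = []
    cell_counts: Counter = Counter()
    for seg in sorted(segments, key=lambda s: s.key):
        n_cells = seg.n_cells
        total = seg.total_reads
        seg_rows.append(
            {
                "chrom": seg.chrom,
                "pos1": seg.cpg_positions[0],
                "pos2": seg.cpg_positions[1],
                "pos3": seg.cpg_positions[2],
                "pos4": seg.cpg_positions[3],
                "n_cells": n_cells,
                "total_reads": total,
                "mean_depth": total / n_cells if n_cells else 0.0,
            }
        )
        for cell in seg.per_cell:
            cell_counts[cell] += 1
    per_segment = pd.DataFrame(
        seg_rows,
        columns=[
            "chrom",
            "pos1",
            "pos2",
            "pos3",
            "pos4",
            "n_cells",
            "total_reads",
            "mean_depth",
        ],
    )
    per_cell = pd.DataFrame(
        sorted(cell_counts.items()), columns=["cell_id", "n_segments"]
    )
    return per_segment, per_cell


def write_segment_table(path: str | Path, segments: Sequence[Segment4CpG]) -> None:
    """Segment table TSV: chrom, pos1..pos4, cell_id, pattern, count."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos1\tpos2\tpos3\tpos4\tcell_id\tpattern\tcount\n")
        for seg in sorted(segments, key=lambda s: s.key):
            p = seg.cpg_positions
            for cell in sorted(seg.per_cell):
                for pattern, count in sorted(seg.per_cell[cell].items()):
                    fh.write(
                        f"{seg.chrom}\t{p[0]}\t{p[1]}\t{p[2]}\t{p[3]}"
                        f"\t{cell}\t{pattern}\t{count}\n"
                    )


def read_segment_table(path: str | Path) -> list[Segment4CpG]:
    # patterns are 0/1 strings; keep leading zeros
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str, "chrom": str})
    table: dict[SegmentKey, Segment4CpG] = {}
    for row in df.itertuples(index=False):
        quad = (int(row.pos1), int(row.pos2), int(row.pos3), int(row.pos4))
        key = (str(row.chrom), quad)
        seg = table.get(key)
        if seg is None:
            seg = Segment4CpG(str(row.chrom), quad)
            table[key] = seg
        seg.per_cell.setdefault(str(row.cell_id), Counter())[str(row.pattern)] += int(
            row.count
        )
    return [table[k] for k in sorted(table)]
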