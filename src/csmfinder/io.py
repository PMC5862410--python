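"""Readers/writers and the shared genomic data model.

Coordinates are 0-based half-open internally (BED convention).  CpG
positions always refer to the cytosine of the plus-strand CpG dyad;
minus-strand calls are shifted one base left on input so that both
strands of a dyad pool into a single site (hairpin analysis, which must
keep strands apart, carries ``strand`` and ``pair_id`` explicitly and is
handled in :mod:`csmfinder.asm_am`).

The canonical on-disk read format ("readtsv") is a TAB-separated table
with columns ``cell_id, chrom, strand, positions, states[, pair_id]``
where ``positions`` is a comma-joined list of increasing coordinates and
``states`` is a 0/1 string of the same length.  Lines starting with
``#`` are comments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AUTOSOME_EXCLUDE = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SiteCount:
    """Methylated/total read counts at one CpG site (m_j <= n_j)."""

    position: int
    meth: int
    total: int

    def __post_init__(self) -> None:
        if self.meth < 0 or self.total < 0 or self.meth > self.total:
            raise ValueError(f"invalid counts meth={self.meth} total={self.total}")


@dataclass(frozen=True)
class ReadPattern:
    """Ordered CpG methylation calls of one sequenced read in one cell.

    ``cpg_positions`` are strictly increasing coordinates on a single
    chromosome; ``states`` are the matching binary calls (1=methylated).
    ``pair_id`` links the two strands of a hairpin read pair.
    """

    cell_id: str
    chrom: str
    cpg_positions: tuple[int, ...]
    states: tuple[int, ...]
    strand: str | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != len(self.states) or not self.cpg_positions:
            raise ValueError("positions/states length mismatch or empty read")
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError("CpG positions must be strictly increasing")
        if any(s not in (0, 1) for s in self.states):
            raise ValueError("states must be 0/1")

    @property
    def pattern(self) -> str:
        return "".join(str(s) for s in self.states)


@dataclass
class RegionCellData:
    """Per-region, per-cell site-level counts feeding all statistics."""

    region: GenomicInterval
    cell_id: str
    sites: list[SiteCount] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def meth_sum(self) -> int:
        return sum(s.meth for s in self.sites)

    @property
    def total_sum(self) -> int:
        return sum(s.total for s in self.sites)


def methylation_level(sites: Sequence[SiteCount]) -> float:
    """Ratio of methylated to total cytosine counts; NaN when no counts."""
    total = sum(s.total for s in sites)
    if total == 0:
        return math.nan
    return sum(s.meth for s in sites) / total


def _normalize_position(position: int, strand: str | None) -> int:
    # minus-strand call sits on the G of the +-strand CpG: shift to the C
    return position - 1 if strand == "-" else position


def read_read_patterns(
    path: str | Path,
    dialect: str = "readtsv",
    autosomes_only: bool = True,
    normalize: bool = True,
) -> list[ReadPattern]:
    """Parse read-level CpG calls.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"readtsv"`` (canonical) or ``"bismark_per_read"`` (one call per
        line: read_id, cell_id, chrom, position, strand, Z/z; grouped by
        read_id).
    autosomes_only:
        Drop reads on sex/mitochondrial chromosomes (default on).
    normalize:
        Map minus-strand positions to the plus-strand C of the CpG dyad.

    Malformed lines are counted and reported as a single warning; the
    offending records are dropped.
    """
    path = Path(path)
    if dialect == "readtsv":
        patterns, n_bad = _read_readtsv(path, normalize=normalize)
    elif dialect == "bismark_per_read":
        patterns, n_bad = _read_bismark_per_read(path, normalize=normalize)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if autosomes_only:
        patterns = [p for p in patterns if p.chrom not in AUTOSOME_EXCLUDE]
    if n_bad:
        warnings.warn(f"{path}: {n_bad} malformed record(s) rejected", stacklevel=2)
    return patterns


def _read_readtsv(path: Path, normalize: bool) -> tuple[list[ReadPattern], int]:
    patterns: list[ReadPattern] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                n_bad += 1
                continue
            cell_id, chrom, strand = fields[0], fields[1], fields[2]
            pair_id = fields[5] if len(fields) > 5 and fields[5] else None
            try:
                positions = tuple(int(x) for x in fields[3].split(","))
                states = tuple(int(c) for c in fields[4])
                if strand not in ("+", "-", "."):
                    raise ValueError(strand)
                strand_val = None if strand == "." else strand
                if normalize:
                    positions = tuple(
                        _normalize_position(p, strand_val) for p in positions
                    )
                patterns.append(
                    ReadPattern(cell_id, chrom, positions, states, strand_val, pair_id)
                )
            except (ValueError, TypeError):
                n_bad += 1
    return patterns, n_bad


def _read_bismark_per_read(path: Path, normalize: bool) -> tuple[list[ReadPattern], int]:
    """Bismark-style per-call table regrouped into reads.

    Columns: read_id, cell_id, chrom, position, strand, call (Z=methylated,
    z=unmethylated, CpG context only).
    """
    calls: dict[str, list[tuple[str, str, int, str, int]]] = {}
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6 or fields[5] not in ("Z", "z"):
                n_bad += 1
                continue
            try:
                pos = int(fields[3])
            except ValueError:
                n_bad += 1
                continue
            calls.setdefault(fields[0], []).append(
                (fields[1], fields[2], pos, fields[4], 1 if fields[5] == "Z" else 0)
            )
    patterns: list[ReadPattern] = []
    for read_id, entries in calls.items():
        cell_id, chrom, _, strand, _ = entries[0]
        if any(e[0] != cell_id or e[1] != chrom for e in entries):
            n_bad += 1
            continue
        strand_val = strand if strand in ("+", "-") else None
        sites = sorted(
            (
                _normalize_position(pos, strand_val) if normalize else pos,
                state,
            )
            for _, _, pos, _, state in entries
        )
        try:
            patterns.append(
                ReadPattern(
                    cell_id,
                    chrom,
                    tuple(p for p, _ in sites),
                    tuple(s for _, s in sites),
                    strand_val,
                    read_id,
                )
            )
        except ValueError:
            n_bad += 1
    return patterns, n_bad


def write_read_patterns(path: str | Path, patterns: Iterable[ReadPattern]) -> None:
    """Write reads in the canonical readtsv dialect.

    In-memory positions are dyad-normalized; on disk, minus-strand
    calls sit on their own strand's C (one base right of the
    plus-strand C), so writing undoes the normalization and
    write-then-read is the identity.
    """
    with open(path, "w") as fh:
        fh.write("# cell_id\tchrom\tstrand\tpositions\tstates\tpair_id\n")
        for p in patterns:
            shift = 1 if p.strand == "-" else 0
            fh.write(
                "\t".join(
                    [
                        p.cell_id,
                        p.chrom,
                        p.strand or ".",
                        ",".join(str(x + shift) for x in p.cpg_positions),
                        p.pattern,
                        p.pair_id or "",
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted intervals (overlaps preserved)."""
    intervals: list[GenomicInterval] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_bad += 1
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValueError:
                n_bad += 1
    if n_bad:
        warnings.warn(f"{path}: {n_bad} malformed BED record(s) rejected", stacklevel=2)
    return sorted(intervals)


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a GTF-lite gene table: chrom, tss, tes, strand, gene_id."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "tss", "tes", "strand", "gene_id"],
        dtype={"chrom": str, "tss": int, "tes": int, "strand": str, "gene_id": str},
    )
    return df


def read_methylation_matrix(path: str | Path) -> pd.DataFrame:
    """Region x sample methylation-level matrix (TSV, first column = region id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
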