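"""Downstream characterization of called CSM loci.

Co-methylation modules: pairwise Pearson correlation of region
methylation profiles across samples (tissues), average-linkage
hierarchical clustering on the distance 1 - r, tree cut at r = 0.75.
Feature enrichment: fold-change of the fraction of CSM regions
overlapping a feature set over the same fraction for control regions.
Histone-peak profiles: each peak scaled to 100 equal bins, a region
incrementing every bin it overlaps, normalized by peak count.  Sequence
features: GC content and CpG observed/expected density from a genome
FASTA.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import GenomicInterval


class CoMethylationClusterer(BaseEstimator, ClusterMixin):
    """Correlation-based hierarchical clustering of methylation profiles.

    Parameters
    ----------
    cutoff:
        Pearson correlation at which the dendrogram is cut (modules are
        flat clusters at distance 1 - cutoff).
    min_module_size:
        Modules smaller than this are relabelled 0 (unassigned).
    method:
        Linkage method (default average).

    Attributes
    ----------
    labels_ : module id per row, 1-based, ordered by decreasing size
        (0 = unassigned).
    correlation_ : the pairwise Pearson correlation matrix.
    """

    def __init__(
        self, cutoff: float = 0.75, min_module_size: int = 2, method: str = "average"
    ):
        self.cutoff = cutoff
        self.min_module_size = min_module_size
        self.method = method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 complete rows")
        if np.isnan(X).any():
            raise ValueError("rows with missing values must be dropped before fit")
        corr = np.corrcoef(X)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        tree = linkage(condensed, method=self.method)
        raw = fcluster(tree, t=1.0 - self.cutoff, criterion="distance")
        self.labels_ = _relabel_by_size(raw, self.min_module_size)
        self.correlation_ = corr
        self.linkage_ = tree
        return self


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    sizes = pd.Series(raw).value_counts()
    labels = np.zeros_like(raw)
    next_id = 1
    for cluster_id, size in sizes.sort_values(ascending=False).items():
        if size >= min_size:
            labels[raw == cluster_id] = next_id
            next_id += 1
    return labels


def comethylation_modules(
    matrix: pd.DataFrame,
    cutoff: float = 0.75,
    min_module_size: int = 2,
    method: str = "average",
) -> pd.Series:
    """Module assignment per region (index preserved; 0 = unassigned).

    Rows with any missing value are dropped (loci without data in every
    sample); constant rows are excluded with a warning since their
    correlation is undefined.
    """
    complete = matrix.dropna(axis=0)
    variances = complete.var(axis=1, ddof=0)
    constant = variances == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) excluded from clustering",
            stacklevel=2,
        )
        complete = complete.loc[~constant]
    if len(complete) < 2:
        raise ValueError("need >= 2 complete, non-constant rows")
    clusterer = CoMethylationClusterer(
        cutoff=cutoff, min_module_size=min_module_size, method=method
    )
    clusterer.fit(complete.to_numpy())
    return pd.Series(clusterer.labels_, index=complete.index, name="module")


def _trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end)
    return trees


def _overlap_fraction(
    regions: Sequence[GenomicInterval], trees: dict[str, IntervalTree]
) -> float:
    if not regions:
        return float("nan")
    hits = sum(
        1
        for r in regions
        if r.chrom in trees and trees[r.chrom].overlap(r.start, r.end)
    )
    return hits / len(regions)


def feature_enrichment(
    csm_regions: Sequence[GenomicInterval],
    control_regions: Sequence[GenomicInterval],
    features: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Fold-change of CSM vs control overlap fraction per feature set.

    Overlap is any >=1 bp intersection; a region counts once per
    feature.  Zero control overlap yields a NaN fold-change sentinel.
    """
    rows = []
    for name, intervals in features.items():
        trees = _trees(intervals)
        f_csm = _overlap_fraction(csm_regions, trees)
        f_ctl = _overlap_fraction(control_regions, trees)
        fold = f_csm / f_ctl if f_ctl else float("nan")
        rows.append(
            {
                "feature": name,
                "frac_csm": f_csm,
                "frac_control": f_ctl,
                "fold_change": fold,
            }
        )
    return pd.DataFrame(rows)


def gene_feature_sets(
    genes: pd.DataFrame,
    cgis: Sequence[GenomicInterval] | None = None,
    promoter_upstream: int = 1000,
    shore_width: int = 2000,
    shelf_width: int = 2000,
) -> dict[str, list[GenomicInterval]]:
    """Standard feature sets from gene models and CpG islands.

    Promoters are the 1 kb upstream of each TSS (strand-aware); CGI
    shores the 2 kb flanking each island and shelves the next 2 kb
    outwards (up to 4 kb from the island).
    """
    features: dict[str, list[GenomicInterval]] = {"promoter": [], "gene_body": []}
    for row in genes.itertuples(index=False):
        if row.strand == "+":
            p_start, p_end = row.tss - promoter_upstream, row.tss
        else:
            p_start, p_end = row.tes, row.tes + promoter_upstream
        if p_start < p_end:
            features["promoter"].append(
                GenomicInterval(row.chrom, max(0, p_start), p_end)
            )
        lo, hi = sorted((row.tss, row.tes))
        if lo < hi:
            features["gene_body"].append(GenomicInterval(row.chrom, lo, hi))
    if cgis is not None:
        features["cgi"] = list(cgis)
        features["cgi_shore"] = []
        features["cgi_shelf"] = []
        for iv in cgis:
            if iv.start > 0:
                features["cgi_shore"].append(
                    GenomicInterval(iv.chrom, max(0, iv.start - shore_width), iv.start)
                )
            features["cgi_shore"].append(
                GenomicInterval(iv.chrom, iv.end, iv.end + shore_width)
            )
            shelf_lo = max(0, iv.start - shore_width - shelf_width)
            if shelf_lo < iv.start - shore_width:
                features["cgi_shelf"].append(
                    GenomicInterval(iv.chrom, shelf_lo, max(0, iv.start - shore_width))
                )
            features["cgi_shelf"].append(
                GenomicInterval(
                    iv.chrom, iv.end + shore_width, iv.end + shore_width + shelf_width
                )
            )
    return features


def peak_profile(
    regions: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    n_bins: int = 100,
) -> np.ndarray:
    """Region frequency across peaks scaled to ``n_bins`` equal bins.

    Each peak is divided into ``n_bins`` equal-sized (fractional) bins;
    a region increments every bin it overlaps.  The profile is the sum
    over peaks divided by the number of peaks.
    """
    if not peaks:
        raise ValueError("peaks must be non-empty")
    trees = _trees(regions)
    profile = np.zeros(n_bins)
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        width = len(peak) / n_bins
        for hit in tree.overlap(peak.start, peak.end):
            lo = max(hit.begin, peak.start)
            hi = min(hit.end, peak.end)
            first = int((lo - peak.start) / width)
            # last base covered is hi - 1
            last = int((hi - 1 - peak.start) / width)
            profile[first : min(last, n_bins - 1) + 1] += 1
    return profile / len(peaks)


def seq_features(
    regions: Sequence[GenomicInterval], fasta_path: str | Path
) -> pd.DataFrame:
    """GC content and CpG observed/expected ratio per region.

    GC = (G + C) / length; CpG O/E = (#CpG * length) / (#C * #G), with 0
    when #C * #G = 0.  Raises when a region lies outside its contig.
    """
    genome = Fasta(str(fasta_path))
    rows = []
    for region in regions:
        if region.chrom not in genome:
            raise KeyError(f"{region.chrom} not in {fasta_path}")
        contig = genome[region.chrom]
        if region.end > len(contig):
            raise ValueError(f"{region} outside contig of length {len(contig)}")
        seq = str(contig[region.start : region.end]).upper()
        n_c = seq.count("C")
        n_g = seq.count("G")
        n_cg = seq.count("CG")
        gc = (n_c + n_g) / len(seq)
        oe = (n_cg * len(seq)) / (n_c * n_g) if n_c * n_g else 0.0
        rows.append(
            {
                "region": f"{region.chrom}:{region.start}-{region.end}",
                "gc_content": gc,
                "cpg_oe": oe,
            }
        )
    return pd.DataFrame(rows)
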