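"""End-to-end CSM pipeline: reads -> segments -> filters -> regions ->
empirical Bayes -> mixture -> LRT/BH -> calls (+ variance table).

Stage order follows the inference workflow: extract 4-CpG segments,
filter known ASM, detect AM (hairpin + single-cell), find bipolar
seeds, extend/merge into candidate regions, coverage-filter, estimate
per-cell beta priors, fit the two-state mixture per region, BH-adjust
the LRT p-values across regions and call CSM; a random-effects variance
table is produced for every fitted region.  All thresholds default to
the study parameterization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .asm_am import detect_am_hairpin, detect_am_single_cell, filter_asm, merge_am
from .ebayes import (
    estimate_prior,
    estimate_region_prior,
    pooled_precision_term,
    posterior,
)
from .io import read_bed, read_read_patterns
from .mixture import assign_membership, call_csm, fit_mixture
from .regions import (
    build_region_cell_data,
    coverage_filter,
    extend_and_merge,
    find_bipolar_seeds,
)
from .segments import extract_4cpg_segments
from .variance import variance_ci, variance_fit


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults reproduce the study settings."""

    flank: int = 100
    min_cells: int = 5
    min_counts: int = 10
    min_cells_call: int = 8
    theta_diff_cutoff: float = 0.3
    alpha: float = 0.05
    em_restarts: int = 10
    em_tol: float = 1e-6
    em_max_iter: int = 500
    seed: int = 0
    autosomes_only: bool = True
    # moment-prior replicate groups: "region" (cells, one shared prior),
    # "cell" (each cell's own sites), or "cell_pooled" (per-cell moments
    # with the across-cell precision correction term)
    prior_scope: str = "region"
    n_boot: int = 1000
    bootstrap_ci: bool = False
    delta_min: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: str | Path | None) -> str | None:
    if path is None:
        return None
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    reads_path: str | Path,
    config: PipelineConfig | None = None,
    hairpin_path: str | Path | None = None,
    asm_bed: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage and return calls, variance table and manifest.

    Returns a dict with keys ``calls`` (DataFrame), ``memberships``
    (DataFrame), ``variance`` (DataFrame), ``fits``, ``candidates``,
    ``manifest``.  When ``outdir`` is given, TSV/JSON outputs are also
    written there.
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}

    reads = read_read_patterns(reads_path, autosomes_only=config.autosomes_only)
    counts["reads"] = len(reads)

    segments = extract_4cpg_segments(reads)
    counts["segments"] = len(segments)

    asm_loci = read_bed(asm_bed) if asm_bed else []
    kept, removed = filter_asm(segments, asm_loci)
    counts["segments_after_asm"] = len(kept)
    counts["segments_removed_asm"] = len(removed)

    am_sc = detect_am_single_cell(kept)
    if hairpin_path:
        hairpin_reads = read_read_patterns(
            hairpin_path, autosomes_only=config.autosomes_only
        )
        am_hp = detect_am_hairpin(hairpin_reads)
    else:
        am_hp = []
    am_loci = merge_am(am_hp, am_sc)
    counts["am_loci"] = len(am_loci)

    seeds = find_bipolar_seeds(kept, am_loci)
    counts["seeds"] = len(seeds)

    merged = extend_and_merge(seeds, kept, flank=config.flank, require_seed=True)
    counts["merged_regions"] = len(merged)

    data = build_region_cell_data(merged, reads)
    candidates = coverage_filter(
        merged, data, min_cells=config.min_cells, min_counts=config.min_counts
    )
    counts["candidate_regions"] = len(candidates)

    fits = []
    variance_rows = []
    membership_rows = []
    for region in candidates:
        if config.prior_scope == "region":
            shared = estimate_region_prior(
                [d.sites for d in region.per_cell.values()]
            )
            priors = {cell: shared for cell in region.per_cell}
        elif config.prior_scope in ("cell", "cell_pooled"):
            pooled = None
            if config.prior_scope == "cell_pooled":
                pooled = pooled_precision_term(
                    [d.sites for d in region.per_cell.values()]
                )
            priors = {
                cell: estimate_prior(d.sites, pooled_term=pooled)
                for cell, d in region.per_cell.items()
            }
        else:
            raise ValueError(f"unknown prior_scope {config.prior_scope!r}")
        fit = fit_mixture(
            region.region_id,
            region.per_cell,
            priors,
            n_init=config.em_restarts,
            tol=config.em_tol,
            max_iter=config.em_max_iter,
            seed=config.seed,
        )
        fits.append(fit)
        posteriors = [
            posterior(priors[c], region.per_cell[c].sites) for c in fit.cell_ids
        ]
        vfit = variance_fit(posteriors)
        ci = (
            variance_ci(posteriors, n_boot=config.n_boot, seed=config.seed)
            if config.bootstrap_ci
            else (np.nan, np.nan)
        )
        variance_rows.append(
            {
                "region_id": fit.region_id,
                "mu": vfit.mu,
                "delta2": vfit.delta2,
                "v_hat": vfit.v_hat,
                "n_cells": vfit.n_cells,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
            }
        )
        labels = assign_membership(fit)
        for cell, label, prob in zip(fit.cell_ids, labels, fit.membership[:, 0]):
            membership_rows.append(
                {
                    "region_id": fit.region_id,
                    "cell_id": cell,
                    "state": int(label),
                    "prob_state1": float(prob),
                }
            )

    calls = call_csm(
        fits,
        theta_diff_cutoff=config.theta_diff_cutoff,
        min_cells_call=config.min_cells_call,
        alpha=config.alpha,
        delta_min=config.delta_min,
    )
    counts["csm_calls"] = sum(c.is_csm for c in calls)

    calls_df = pd.DataFrame(
        [
            {
                "region_id": f.region_id,
                "lambda1": f.lam[0],
                "theta1": f.theta[0],
                "theta2": f.theta[1],
                "theta_diff": f.theta_diff,
                "observed_diff": f.observed_diff,
                "loglik": f.loglik,
                "loglik_null": f.loglik_null,
                "p_value": f.p_value,
                "p_adjusted": f.p_adjusted,
                "n_cells": f.n_cells_with_data,
                "is_csm": c.is_csm,
                "reasons": ",".join(c.reasons),
            }
            for f, c in zip(fits, calls)
        ]
    )
    variance_df = pd.DataFrame(variance_rows)
    membership_df = pd.DataFrame(membership_rows)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "inputs": {
            "reads": _checksum(reads_path),
            "hairpin": _checksum(hairpin_path),
            "asm_bed": _checksum(asm_bed),
        },
        "stage_counts": counts,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        calls_df.to_csv(outdir / "csm_calls.tsv", sep="\t", index=False)
        variance_df.to_csv(outdir / "variance.tsv", sep="\t", index=False)
        membership_df.to_csv(outdir / "memberships.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return {
        "calls": calls_df,
        "variance": variance_df,
        "memberships": membership_df,
        "fits": fits,
        "candidates": candidates,
        "manifest": manifest,
    }
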