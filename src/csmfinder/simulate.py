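"""Simulation protocol, model-assessment harness and fixture generator.

Two generators live here.

``simulate_region`` follows the study protocol for assessing the
mixture model: two cell subpopulations with methylation probabilities
theta^(1) >= theta^(2), mixing proportion lambda, per-site read depths
drawn from a Poisson (zero depth = missing site) and methylated counts
drawn binomially.  Estimated parameters are "accurate" when they fall
within 1e-2 of the truth; because the realized composition of a finite
cell sample deviates from lambda by far more than that, accuracy for
lambda is judged against the realized hyper-state fraction (both are
recorded).

``make_synthetic_methylome`` emits a full read-level fixture for
end-to-end tests: planted CSM, ASM, AM and null loci on one chromosome,
written in the canonical readtsv dialect together with hairpin read
pairs and truth BED files.  CSM/ASM/AM loci are allele-structured (each
cell carries two allele patterns; reads sample an allele and add a
small per-call error), which is what makes the within-cell AM filter
meaningful; null loci use read-level binomial sampling at a common
locus-wide probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ebayes import estimate_prior_arrays
from .io import GenomicInterval, ReadPattern, write_bed, write_read_patterns
from .mixture import BetaBinomialMixture, bh_adjust


@dataclass
class SimConfig:
    """Study-protocol simulation settings for one region."""

    n_cells: int = 20
    n_sites: int = 4
    mean_depth: float = 20.0
    lam: float | str = "random"  # U[0,1] when "random"
    theta: tuple[float, float] | str = "random"  # each U[0,1] when "random"
    missing_rate: float = 0.0
    n_reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if isinstance(self.lam, float) and not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")


@dataclass
class SimResult:
    """Per-replicate truths/estimates plus aggregate assessment metrics."""

    table: pd.DataFrame
    accuracy_tol: float
    fraction_accurate: float
    fdr: float
    tpr: float
    fpr: float
    ppv: float
    roc: pd.DataFrame = field(repr=False, default=None)


def simulate_region(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate one region: returns (meths, totals, truth).

    ``meths``/``totals`` are (n_cells, n_sites) integer arrays; zero
    totals encode missing sites.  ``truth`` records lambda (parameter
    and realized fraction), the state probabilities and assignments.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam = float(rng.uniform()) if cfg.lam == "random" else float(cfg.lam)
    if cfg.theta == "random":
        t = rng.uniform(size=2)
        theta1, theta2 = float(t.max()), float(t.min())
    else:
        theta1, theta2 = (float(max(cfg.theta)), float(min(cfg.theta)))
    states = (rng.uniform(size=cfg.n_cells) >= lam).astype(int)  # 0=hyper, 1=hypo
    theta_cell = np.where(states == 0, theta1, theta2)
    totals = rng.poisson(cfg.mean_depth, size=(cfg.n_cells, cfg.n_sites))
    if cfg.missing_rate > 0:
        mask = rng.uniform(size=totals.shape) < cfg.missing_rate
        totals = np.where(mask, 0, totals)
    meths = rng.binomial(totals, theta_cell[:, None])
    truth = {
        "lam": lam,
        "lam_realized": float((states == 0).mean()),
        "theta1": theta1,
        "theta2": theta2,
        "theta_diff": theta1 - theta2,
        "states": states,
    }
    return meths, totals, truth


def fit_simulated_region(
    meths: np.ndarray,
    totals: np.ndarray,
    n_init: int = 4,
    seed: int | None = None,
    prior_scope: str = "region",
) -> dict:
    """Empirical-Bayes priors + mixture fit on simulated per-site counts.

    ``prior_scope`` selects the moment-prior replicate groups: "region"
    (cells; one shared prior — the default) or "cell" (each cell's own
    sites).
    """
    n_cells = meths.shape[0]
    priors = np.ones((n_cells, 2))
    X = np.column_stack([meths.sum(axis=1), totals.sum(axis=1)]).astype(float)
    with_data = X[:, 1] > 0
    if prior_scope == "region":
        prior = estimate_prior_arrays(X[with_data, 0], X[with_data, 1])
        priors[:] = (prior.alpha, prior.beta)
    elif prior_scope == "cell":
        for i in range(n_cells):
            n = totals[i]
            keep = n > 0
            prior = estimate_prior_arrays(
                meths[i][keep].astype(float), n[keep].astype(float)
            )
            priors[i] = (prior.alpha, prior.beta)
    else:
        raise ValueError(f"unknown prior_scope {prior_scope!r}")
    model = BetaBinomialMixture(n_init=n_init, random_state=seed)
    model.fit(X[with_data], priors=priors[with_data])
    return {
        "lam_hat": float(model.weights_[0]),
        "theta1_hat": float(model.thetas_[0]),
        "theta2_hat": float(model.thetas_[1]),
        "theta_diff_hat": float(model.thetas_[0] - model.thetas_[1]),
        "p_value": model.p_value_,
        "n_cells_with_data": int(with_data.sum()),
        "converged": model.converged_,
    }


def run_assessment(
    n_reps: int,
    n_cells: int = 20,
    n_sites: int = 4,
    mean_depth: float = 20.0,
    lam_range: tuple[float, float] = (0.2, 0.8),
    min_theta_diff: float = 0.0,
    null: bool = False,
    seed: int | None = None,
    n_init: int = 4,
) -> pd.DataFrame:
    """Replicated simulate-and-fit runs for model assessment.

    ``null=True`` simulates one-state regions (theta1 == theta2 drawn
    U[0,1]); otherwise two states are drawn U[0,1] subject to
    ``min_theta_diff``.  ``lam_range`` keeps both states populated; the
    study draws lambda from U[0,1], which regularly leaves one state
    empty in a finite cell sample.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        if null:
            t = float(rng.uniform())
            theta = (t, t)
        else:
            while True:
                t = rng.uniform(size=2)
                if t.max() - t.min() >= min_theta_diff:
                    theta = (float(t.max()), float(t.min()))
                    break
        lam = float(rng.uniform(*lam_range))
        cfg = SimConfig(
            n_cells=n_cells, n_sites=n_sites, mean_depth=mean_depth,
            lam=lam, theta=theta,
        )
        meths, totals, truth = simulate_region(cfg, rng)
        est = fit_simulated_region(
            meths, totals, n_init=n_init, seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "rep": rep,
                "lam": truth["lam"],
                "lam_realized": truth["lam_realized"],
                "theta1": truth["theta1"],
                "theta2": truth["theta2"],
                "theta_diff": truth["theta_diff"],
                **est,
            }
        )
    return pd.DataFrame(rows)


def evaluate(
    fits: pd.DataFrame,
    truths: pd.DataFrame | None = None,
    accuracy_tol: float = 1e-2,
    theta_diff_cutoff: float = 0.3,
    alpha: float = 0.05,
    true_csm_rule: float | None = None,
    n_roc_points: int = 51,
) -> SimResult:
    """Assess fitted replicates against their truths.

    ``fits`` may already contain the truth columns (output of
    :func:`run_assessment`); otherwise ``truths`` supplies them row for
    row (hard error on length mismatch).  A replicate counts as
    accurate when max(|lam_hat - lam_realized|, |theta_hat - theta|)
    over both states is below ``accuracy_tol``.  Calling a replicate
    CSM uses BH-adjusted p < alpha and estimated theta difference >=
    the cutoff; the ground-truth label is a true theta difference >=
    ``true_csm_rule`` (default: the same cutoff).  The ROC sweeps the
    theta-difference cutoff at fixed alpha.
    """
    if truths is not None:
        if len(truths) != len(fits):
            raise ValueError("fits and truths length mismatch")
        table = pd.concat(
            [truths.reset_index(drop=True), fits.reset_index(drop=True)], axis=1
        )
    else:
        table = fits.copy().reset_index(drop=True)

    err = np.maximum.reduce(
        [
            (table["lam_hat"] - table["lam_realized"]).abs().to_numpy(),
            (table["theta1_hat"] - table["theta1"]).abs().to_numpy(),
            (table["theta2_hat"] - table["theta2"]).abs().to_numpy(),
        ]
    )
    table["max_error"] = err
    table["accurate"] = err < accuracy_tol
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())

    rule = theta_diff_cutoff if true_csm_rule is None else true_csm_rule
    truth_pos = (table["theta_diff"] >= rule).to_numpy()
    called = (
        (table["p_adjusted"] < alpha)
        & (table["theta_diff_hat"] >= theta_diff_cutoff)
    ).to_numpy()
    table["called_csm"] = called

    tp = int((called & truth_pos).sum())
    fp = int((called & ~truth_pos).sum())
    fn = int((~called & truth_pos).sum())
    tn = int((~called & ~truth_pos).sum())
    fdr = fp / (tp + fp) if tp + fp else 0.0
    tpr = tp / (tp + fn) if tp + fn else math.nan
    fpr = fp / (fp + tn) if fp + tn else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan

    roc_rows = []
    for cut in np.linspace(0.0, 1.0, n_roc_points):
        c = (
            (table["p_adjusted"] < alpha) & (table["theta_diff_hat"] >= cut)
        ).to_numpy()
        tp_c = int((c & truth_pos).sum())
        fp_c = int((c & ~truth_pos).sum())
        roc_rows.append(
            {
                "cutoff": cut,
                "tpr": tp_c / truth_pos.sum() if truth_pos.any() else math.nan,
                "fpr": fp_c / (~truth_pos).sum() if (~truth_pos).any() else math.nan,
            }
        )
    return SimResult(
        table=table,
        accuracy_tol=accuracy_tol,
        fraction_accurate=float(table["accurate"].mean()),
        fdr=fdr,
        tpr=tpr,
        fpr=fpr,
        ppv=ppv,
        roc=pd.DataFrame(roc_rows),
    )


def accuracy_curve(
    reps_per_bin: int = 1000,
    bin_width: float = 0.05,
    n_cells: int = 20,
    n_sites: int = 4,
    mean_depth: float = 600.0,
    lam_range: tuple[float, float] = (0.2, 0.8),
    accuracy_tol: float = 1e-2,
    seed: int | None = None,
    n_init: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy fraction as a function of the true theta difference.

    The true difference is drawn uniformly within each bin of width
    ``bin_width`` covering (0, 1); theta2 is then uniform on
    [0, 1 - diff].  Returns ``(curve, table)``: the binned accuracy
    fractions with their binomial standard errors, and the full
    per-replicate table (also the basis for the estimated-vs-true
    correlation).  A replicate is accurate when lambda and both state
    probabilities are each within ``accuracy_tol`` of the truth.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, 1.0 + 1e-9, bin_width)
    rows = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        for rep in range(reps_per_bin):
            diff = float(rng.uniform(lo, min(hi, 1.0 - 1e-6)))
            theta2 = float(rng.uniform(0.0, 1.0 - diff))
            theta = (theta2 + diff, theta2)
            lam = float(rng.uniform(*lam_range))
            cfg = SimConfig(
                n_cells=n_cells, n_sites=n_sites, mean_depth=mean_depth,
                lam=lam, theta=theta,
            )
            meths, totals, truth = simulate_region(cfg, rng)
            est = fit_simulated_region(
                meths, totals, n_init=n_init, seed=int(rng.integers(2**31))
            )
            err = max(
                abs(est["lam_hat"] - truth["lam_realized"]),
                abs(est["theta1_hat"] - truth["theta1"]),
                abs(est["theta2_hat"] - truth["theta2"]),
            )
            rows.append(
                {
                    "bin": b,
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "theta_diff": truth["theta_diff"],
                    "theta_diff_hat": est["theta_diff_hat"],
                    "max_error": err,
                    "accurate": err < accuracy_tol,
                }
            )
    table = pd.DataFrame(rows)
    curve = (
        table.groupby("bin")
        .agg(
            bin_lo=("bin_lo", "first"),
            bin_hi=("bin_hi", "first"),
            accuracy=("accurate", "mean"),
            n=("accurate", "size"),
        )
        .reset_index()
    )
    curve["se"] = np.sqrt(
        np.clip(curve["accuracy"] * (1 - curve["accuracy"]), 0.0, None) / curve["n"]
    )
    return curve, table


# ---------------------------------------------------------------------------
# synthetic methylome fixture


@dataclass
class MethylomeSpec:
    """Planted-locus layout for the synthetic read-level fixture."""

    n_csm: int = 50
    n_asm: int = 20
    n_am: int = 20
    n_null: int = 200
    n_cells: int = 19
    reads_per_locus: int = 15
    n_cpgs_per_locus: int = 6
    cpg_spacing: int = 10
    locus_spacing: int = 1000
    chrom: str = "chr1"
    csm_theta: tuple[float, float] = (0.9, 0.3)
    csm_lam: float = 0.5
    asm_theta: tuple[float, float] = (0.97, 0.03)
    error_rate: float = 0.005
    cell_coverage: float = 1.0
    hairpin_pairs_per_am: int = 3

    def __post_init__(self) -> None:
        if self.locus_spacing <= self.n_cpgs_per_locus * self.cpg_spacing + 2 * 100:
            raise ValueError("loci would overlap after flank extension")


def make_synthetic_methylome(
    outdir: str | Path, spec: MethylomeSpec | None = None, seed: int = 0
) -> dict:
    """Write a deterministic synthetic methylome fixture.

    Emits ``reads.tsv`` (single-cell reads), ``hairpin.tsv`` (hairpin
    read pairs with 1111/0000 discordance at AM loci plus concordant
    decoys), and truth BEDs ``truth_csm.bed``, ``truth_asm.bed``,
    ``truth_am.bed``, ``truth_null.bed``.  ``truth_asm.bed`` doubles as
    the known-ASM annotation input of the pipeline.  Returns a dict of
    paths plus the truth table.
    """
    spec = spec or MethylomeSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    loci = (
        ["csm"] * spec.n_csm + ["asm"] * spec.n_asm + ["am"] * spec.n_am
        + ["null"] * spec.n_null
    )
    rng.shuffle(loci)

    cells = [f"cell{i:02d}" for i in range(spec.n_cells)]
    reads: list[ReadPattern] = []
    hairpin: list[ReadPattern] = []
    truth_rows = []
    pair_counter = 0

    for idx, kind in enumerate(loci):
        start = 1000 + idx * spec.locus_spacing
        positions = tuple(
            start + k * spec.cpg_spacing for k in range(spec.n_cpgs_per_locus)
        )
        interval = GenomicInterval(spec.chrom, positions[0], positions[-1] + 1)
        truth_rows.append(
            {"locus": idx, "kind": kind, "chrom": spec.chrom,
             "start": interval.start, "end": interval.end}
        )

        if kind == "null":
            theta_locus = float(rng.uniform())
        if kind == "csm" or kind == "am":
            hyper = rng.uniform(size=spec.n_cells) < spec.csm_lam
        covered = rng.uniform(size=spec.n_cells) < spec.cell_coverage

        for ci, cell in enumerate(cells):
            if not covered[ci]:
                continue
            if kind == "null":
                # read-level binomial sampling at the common locus probability
                alleles = None
            else:
                if kind == "asm":
                    t = spec.asm_theta
                else:  # csm / am: both alleles share the cell's state
                    tc = spec.csm_theta[0] if hyper[ci] else spec.csm_theta[1]
                    t = (tc, tc)
                alleles = (
                    rng.uniform(size=spec.n_cpgs_per_locus) < t[0],
                    rng.uniform(size=spec.n_cpgs_per_locus) < t[1],
                )
            for ri in range(spec.reads_per_locus):
                w = int(rng.integers(0, spec.n_cpgs_per_locus - 3))
                window = positions[w : w + 4]
                if alleles is None:
                    states = rng.uniform(size=4) < theta_locus
                else:
                    allele = alleles[int(rng.integers(0, 2))]
                    states = allele[w : w + 4].copy()
                    flips = rng.uniform(size=4) < spec.error_rate
                    states = states ^ flips
                reads.append(
                    ReadPattern(
                        cell, spec.chrom, window, tuple(int(s) for s in states), "+"
                    )
                )

        if kind == "am":
            # pairs span the whole locus so every 4-CpG window carries
            # the discordant 1/0 evidence, as genome-wide hairpin
            # coverage of an AM locus would
            n = spec.n_cpgs_per_locus
            for _ in range(spec.hairpin_pairs_per_am):
                pair_counter += 1
                pid = f"hp{pair_counter:06d}"
                hairpin.append(
                    ReadPattern("hairpin", spec.chrom, positions, (1,) * n, "+", pid)
                )
                # minus-strand mate carries dyad-normalized positions in
                # memory; the writer emits its G coordinates on disk
                hairpin.append(
                    ReadPattern("hairpin", spec.chrom, positions, (0,) * n, "-", pid)
                )
        elif kind == "null" and idx % 10 == 0:  # concordant decoy pairs
            pair_counter += 1
            pid = f"hp{pair_counter:06d}"
            window = positions[0:4]
            st = tuple(int(x) for x in (rng.uniform(size=4) < theta_locus))
            hairpin.append(
                ReadPattern("hairpin", spec.chrom, window, st, "+", pid)
            )
            hairpin.append(
                ReadPattern("hairpin", spec.chrom, window, st, "-", pid)
            )

    truth = pd.DataFrame(truth_rows)
    paths = {
        "reads": outdir / "reads.tsv",
        "hairpin": outdir / "hairpin.tsv",
        "truth_table": outdir / "truth.tsv",
    }
    write_read_patterns(paths["reads"], reads)
    write_read_patterns(paths["hairpin"], hairpin)
    truth.to_csv(paths["truth_table"], sep="\t", index=False)
    for kind in ("csm", "asm", "am", "null"):
        sub = truth[truth["kind"] == kind]
        path = outdir / f"truth_{kind}.bed"
        write_bed(
            path,
            [
                GenomicInterval(r.chrom, r.start, r.end)
                for r in sub.itertuples(index=False)
            ],
        )
        paths[f"truth_{kind}"] = path
    paths["truth"] = truth
    return paths
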