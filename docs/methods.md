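# Methods

This note records the model, the estimation choices, and the
limitations of the implementation, in the order the pipeline runs.

## Data model and coordinates

All intervals are 0-based half-open. CpG dyads are addressed by the
cytosine of the plus strand; minus-strand calls are shifted one base
left on input so that both strands of a dyad pool into one site.
Hairpin bisulfite reads are the one place strand identity matters, so
they carry `strand` and `pair_id` and are never pooled. Sex and
mitochondrial chromosomes are excluded by default (`autosomes_only`).

## Segments, ASM and AM

A 4-CpG segment is a window of four consecutive CpG sites observed on
one read; a read covering c CpGs yields max(0, c − 3) windows, and
identical position quadruples collapse across reads/cells into one
per-cell pattern tally. "Consecutive" means consecutive within the
read; no genomic span cap is applied by default (`max_span` exposed).

ASM exclusion is by position membership: a segment is removed when any
of its four CpG coordinates falls inside a known ASM interval. This is
stricter than span overlap and matches CpG-resolved ASM annotations.

AM detection has two evidence routes, merged by segment key with
provenance: (i) hairpin — some read pair shows `1111` on one strand
and `0000` on the mate over the same window; (ii) single cell — one
cell's tally contains both `1111` and `0000`. Bipolarity *across*
cells is deliberately not AM: it is the CSM seed signal.

## Candidate regions

Seeds are ASM-filtered, non-AM segments with a fully methylated read
in one cell and a fully unmethylated read in a different cell. Seeds
and all other ASM-filtered segments are extended ±100 bp (span
[pos1, pos4+1) before extension) and strictly-overlapping extended
intervals are unioned; merged intervals containing no seed are dropped
(the same machinery without the seed requirement produces the control
universe). "Ten cytosine counts" is read as the total CpG observation
count Σ_j n_ji of a cell inside the region; site counts are rebuilt
from *all* reads overlapping the merged region, not only 4-CpG-segment
reads, because the beta-binomial layer consumes per-CpG counts.

## Empirical-Bayes layer

Within region r, cell i: m_ji ~ Binomial(n_ji, θ_i), θ_i ~ Beta(α, β),
hence posterior Beta(Σm + α, Σn − Σm + β) with the closed-form mean
and variance used throughout. Missing sites contribute zero counts.

The prior is estimated by the beta-binomial method of moments on
weighted level moments: μ̂ = Σ w e / Σ w, s² = Σ w (e − μ̂)² / Σ w and

    M̂ = (μ̂(1 − μ̂) − s²) / (s² − μ̂(1 − μ̂) · C),

α̂ = μ̂ M̂, β̂ = (1 − μ̂) M̂, with the flat Beta(1,1) fallback whenever M̂
is non-positive or non-finite (which includes s² = 0 and the
single-replicate case).

**Prior scope.** The moment estimator needs replicate groups. The
default (`prior_scope="region"`) treats the *cells* of a region as the
groups: e_i is the cell-level methylation fraction, w_i = T_i the
cell's total count and C = mean_i(1/T_i), giving one shared (α̂, β̂)
per region. The alternative scope (`prior_scope="cell"`) treats the
CpG sites within one region-cell as groups (e_j = m_j/n_j, w_j = n_j,
C = mean_j(1/n_j)), giving per-cell priors; `"cell_pooled"` keeps
per-cell moments but averages the correction term over cells. The
region scope is the default because a per-cell prior estimated from
that same cell's handful of sites re-enters the mixture likelihood as
if it were independent information; in simulation this double counting
inflates the null rejection rate of the LRT by an order of magnitude,
while the region-scope test is conservative (measured rejection ≈
0.001–0.003 at nominal 0.05). The region scope is also the reading
under which the across-cell sum printed in the precision estimator is
self-consistent.

## Two-state mixture and calling

Cells in a region belong to K = 2 latent states with proportions λ_k
and state methylation probabilities θ⁽¹⁾ ≥ θ⁽²⁾. The contribution of
cell i under state k is its posterior beta density evaluated at θ⁽ᵏ⁾:

    Pr(i | θ) = θ^(a_i−1) (1 − θ)^(b_i−1) / B(a_i, b_i),

a per-cell constant apart, so the E-step responsibilities and the
closed M-step

    λ_k = mean_i γ_ik,
    θ⁽ᵏ⁾ = Σ_i γ_ik (a_i − 1) / Σ_i γ_ik (a_i + b_i − 2)

follow; θ updates are clamped to [1e-6, 1 − 1e-6] (negative numerators
can arise when a prior shape is below 1). Convergence is |Δ log L| <
1e-6 within 500 iterations. Initialization uses 10 restarts: a median
split of the posterior means, the one-state optimum (an EM fixed point,
which guarantees the fitted likelihood is never below the null), and
random memberships. States are relabelled θ-descending; an empty state
flags the fit degenerate.

The LRT statistic 2(ℓ₂ − ℓ₁) is referred to χ² with 2 df (3 free
parameters vs 1). Mixture regularity fails at the boundary, so this
reference is a convention, not an asymptotic truth; in simulation it
is conservative under the null, and a parametric bootstrap
(`parametric_bootstrap_pvalue`) is available. P-values are BH-adjusted
across the full region set. A region is called CSM iff adjusted
p < 0.05, θ⁽¹⁾ − θ⁽²⁾ ≥ 0.3 and ≥ 8 cells carry data. The observed
group difference (posterior-mean gap between assigned groups) is
reported, and an optional `delta_min` screen on it can be enabled;
by default it does not gate calls. Cell assignment is
Pr(Y=1) ≥ Pr(Y=2) → state 1 (ties to the hyper-methylated state).

The 0.3 cut-off is where the accuracy-vs-separation curve plateaus in
the assessment harness (below), matching its role as the smallest
separation the model resolves reliably.

## Cell-to-cell variance

Per region, each cell contributes its posterior mean θ_i and variance
V_i. The between-cell variance Δ² is the non-iterative
DerSimonian–Laird moment estimate, truncated at zero; μ̂ is the
w* = 1/(V_i + Δ²)-weighted mean and V̂ = 1/Σw*. Fewer than two cells
yields an undefined sentinel. The 95% CI is a percentile bootstrap
over cells (default 1000 replicates), deterministic under a seed.
The bootstrap unit and the CI type are implementation choices; REML or
iterative heterogeneity estimators are out of scope.

## Simulation and assessment harness

`simulate_region` follows the assessment protocol: two subpopulations,
λ and the state probabilities drawn from U[0,1] unless fixed, per-site
depths Poisson (zero depth = missing), methylated counts binomial; an
optional independent masking rate exists for stress tests and is off
by default. An estimate is "accurate" when it is within 1e-2 of the
truth. Two deliberate interpretation choices:

- λ accuracy is judged against the *realized* fraction of hyper-state
  cells, which is the estimable quantity — a 20-cell draw deviates
  from the population λ by ≈ 0.11 s.d., far above the 1e-2 rule.
- The recovery and curve harnesses draw λ from U(0.2, 0.8) so that
  both states are populated; with λ ~ U[0,1] a 20-cell sample leaves
  one state empty with probability ≈ 2/21, making that state's θ
  unidentifiable regardless of the estimator.

The accuracy curve (`accuracy_curve`) bins the true θ⁽¹⁾ − θ⁽²⁾ in
steps of 0.05 with the difference drawn uniformly inside each bin. It
uses N = 20 cells, 4 sites and mean depth 600: the curve can only
plateau once per-parameter sampling noise sits below the 1e-2 rule
(at depth 20 the noise floor is ≈ 0.015 s.d. and the "accuracy"
keeps climbing as the θs approach the boundaries); at depth 600 the
only remaining obstacle is state separation, which resolves by ≈ 0.3.
Monotonicity and plateau checks in the tests allow two binomial
standard errors for the finite replicate counts.

`evaluate` computes the accuracy fraction, BH-adjusted calling at the
configured operating point (FDR/TPR/FPR/PPV) and a ROC curve obtained
by sweeping the θ-difference cut-off at fixed α.

## Synthetic methylome fixture

`make_synthetic_methylome` writes a read-level methylome with planted
CSM, ASM, AM and homogeneous ("null") loci on one chromosome (defaults:
50/20/20/200 loci of 6 CpGs spaced 10 bp, 1 kb apart; 19 cells, 15
reads per cell per locus). CSM/ASM/AM loci are allele-structured: each
cell carries two allele patterns (drawn per-CpG from the cell-state
probability — 0.9/0.3 for CSM/AM states, 0.97/0.03 for the two ASM
alleles) and reads sample an allele with a 0.5% per-call error. This
is what gives the within-cell AM filter something real to act on: a
read from a methylated allele essentially never reads `0000`.
Homogeneous loci instead draw every read call independently at a
locus-wide probability, emulating a locus with unstable, single-state
methylation. AM loci look CSM-like in the single-cell reads but carry
full-locus discordant hairpin pairs, so recovering zero of them tests
the hairpin filter, not the generator. The ASM truth BED doubles as
the pipeline's known-ASM input. All outputs are deterministic per
seed.

What passing these tests does *not* show: real scBS-seq has uneven
coverage, bisulfite conversion failure, mapping artefacts and
correlated neighbouring CpGs; the generator models none of these, so
end-to-end recall/precision here measure the pipeline's logic, not
expected performance on real libraries.

## Numerical choices and degenerate inputs

- EM: tol 1e-6 on the log-likelihood, 500 iterations, 10 restarts,
  per-region seeds derived via CRC32 of the region id (stable across
  processes).
- θ and λ clamps at 1e-6; LRT statistics below −1e-8 raise (EM
  failure), tiny negative values truncate to 0.
- Moment priors: M̂ ≤ 0, non-finite, or a zero shape parameter all
  fall back to Beta(1,1); all-missing cells are flagged `no_data`.
- Methylation level of an empty site set is NaN, never 0.
- BH is statsmodels' `fdr_bh`; correlation clustering drops rows with
  missing values and excludes constant rows (undefined correlation).
- Bootstrap CIs resample cells with replacement; percentile method.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the harness at 500
replicates (recovery), 20 × 1000 replicates (accuracy curve), 1000
replicates (null calibration), a 290-locus methylome (end-to-end), and
100–1000 draws for the oracle comparisons. These sizes give binomial
standard errors comfortably inside the tolerances they are checked
against while keeping a full run in the low minutes on one core.

## Known limitations

- K is fixed at 2; regions hosting more than two methylation states
  are reported as their best two-state split.
- The χ²(2 df) LRT reference is conservative rather than exact.
- The ASM filter is only as complete as the supplied annotation;
  stochastic ASM outside it will surface as CSM candidates.
- Upstream read processing (alignment, deduplication, contamination
  removal) is out of scope; inputs are assumed to be clean read-level
  CpG calls.
- The per-cell prior scope is retained for comparison but is known to
  be anti-conservative (see "Prior scope").
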