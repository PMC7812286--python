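# Methods

## Scope and data model

`dnbtip` analyses a replicated expression time series: treated subjects
sampled at an ordered set of timepoints (default weeks 3, 5, 9, 14, 17
with five replicates each) and untreated controls at a subset of them
(default weeks 3, 9, 17 with three replicates). Input is a genes ×
samples matrix of raw counts or log2 intensities plus a sample sheet.
Counts are converted to `log2(count + 1)` on ingest and every downstream
statistic operates on the log2 scale; correlations and standard
deviations on raw counts would be dominated by the mean–variance
relationship, while the log2 transform approximately stabilises the
replicate variance. Gene identifiers are opaque case-sensitive strings;
identifier conversion (e.g. paralog mapping between annotation sources)
is only ever applied through an explicit, user-supplied alias table.

## Control adjustment

Treated samples are centred gene-wise on the mean over *all* control
samples, pooled across control timepoints. Pooling is the default
because the control series is sparse (three timepoints, three replicates
each) and a per-gene pooled mean is the lowest-variance estimate of the
developmental baseline; a time-matched mode (nearest control timepoint)
is available behind a flag, and skipping adjustment entirely must be
requested explicitly. Centering is lossless (adding the stored control
means back reproduces the input to 1e-12) and does not change
within-timepoint correlations or SDs; its purpose is to keep
developmental drift out of the post- vs pre-tipping fold changes and the
reported "adjusted" expression directions.

## Per-timepoint statistics and the composite index

At a timepoint *t* with *r ≥ 3* treated replicates, the package computes
per gene the sample SD (denominator *n* − 1) and, per gene pair, the
absolute Pearson correlation across the *r* replicates. Genes constant
across replicates get SD 0 and all their correlations defined as 0 (the
count is logged). For a candidate module *M* inside a universe of *n*
genes:

- `PCC_i` — mean |PCC| over unordered within-module pairs,
- `PCC_o` — mean |PCC| over all module × outside pairs,
- `SD_i` — mean SD over module genes,
- `CI = PCC_i · SD_i / max(PCC_o, ε)` with ε = 1e-6 guarding the
  degenerate case of an uncorrelated outside.

CI is linear in the expression scale through SD_i (multiplying the data
by *c* multiplies CI by *c*) and dimensionless in the correlations.

## Dominant-group discovery

The DNB literature specifies the three criteria and the composite index
but not the grouping algorithm. The discovery implemented here is the
package's own reconstruction, built in two stages and applied
identically to observed and permuted data:

1. **Tree scan.** Average-linkage hierarchical clustering on the
   dissimilarity 1 − |PCC| at timepoint *t*; the CI of *every* tree node
   whose size lies in a window (see below) is evaluated in O(n²) total
   by propagating row-sum vectors up the merge tree. The top nodes by
   CI (default 8) become seeds. A classical fixed-height tree cut is
   retained behind `cut_rule="height"` and in `candidate_modules`, but a
   fixed cut is not reliable at small replicate counts: with r = 5 the
   *null* expectation of |PCC| is 4/(3π) ≈ 0.42, so distances between
   unrelated genes concentrate near 0.58 and any cut in (0.4, 0.6)
   produces large chance clusters that swallow real modules.
2. **Factor refinement.** A DNB module is, by hypothesis, a rank-1
   collective fluctuation: members share one latent factor. Each seed
   is refined by iterating (i) estimate the factor as the dominant right
   singular vector of the members' centred replicate profiles, (ii)
   score every gene by its loading — the projection of its centred
   profile onto the factor, which is the product of its correlation with
   the factor and its SD, exactly the joint evidence that separates true
   members from genes that merely chance-correlate with the factor at
   r = 5 — and (iii) keep genes whose |loading| exceeds 2.5 robust
   (MAD-normalised) standard deviations of the all-gene loading
   distribution. The refined candidate with the highest CI is the
   dominant group at *t*.

**Size window.** The minimum dominant-group size defaults to 3·r (15 at
five replicates): with r-sample correlation estimates, clusters of up to
about 3r genes reach near-perfect average |PCC| by selection alone, so
smaller groups carry no evidential weight; an upper bound of half the
universe excludes degenerate "module ≈ everything" solutions. Both are
configurable.

## Tipping call and permutation null

The tipping candidate is the CI-argmax over timepoints of the dominant
groups (ties break toward the earliest timepoint — the conservative
choice for an early-warning signal). Its significance is assessed by
re-running the *entire* discovery on permuted data: per gene,
independently, the per-timepoint replicate blocks are shuffled across
timepoints and the replicate order within each relocated block is
re-shuffled. This destroys all cross-gene time-localised co-fluctuation
while preserving each gene's marginal distribution and its multiset of
per-timepoint variances. (An unconstrained per-gene shuffle would
scatter heavy values — e.g. variance-inflated tipping-time replicates or
post-tipping shifts — across timepoints; at five replicates, two genes
that happen to place outliers in the same sample acquire near-perfect
spurious correlation, and the null would dominate any real signal.)
With N permutations (default 200) the p-value is
(1 + #{null max-CI ≥ observed max-CI}) / (N + 1), and the tipping time
is reported only when p < α (default 0.05). The permutation loop may
stop early once enough exceedances have accumulated that p ≥ α is
guaranteed; the reported p is then conservative and the number of
permutations actually used is recorded.

The three DNB criteria are additionally reported per timepoint as flags
comparing the dominant group's PCC_i, SD_i and PCC_o at that timepoint
against the same group's mean statistics at the other timepoints.

## Synthetic data

The generator plants the structure the analysis assumes. Per gene, a
baseline log2 level μ_g ~ N(7, 1.5²) and i.i.d. replicate noise of SD
σ (default 0.5 log2 units, a typical replicate SD for bulk expression).
Module genes at the tipping time share one standard-normal factor *z*
per replicate sample:

    value = μ_g + λ·z + ε,  λ² = ρ_in·v·σ²,  Var(ε) = (1 − ρ_in)·v·σ²,

which gives exact pairwise correlation ρ_in in expectation, variance
inflation *v*, and a positive-semi-definite implied correlation matrix
by construction. Defaults ρ_in = 0.9, v = 3, 20 module genes among 500.
An optional weak global factor gives background correlation ρ_bg to all
genes *except* the module at the tipping time, making PCC_o decrease
strictly at the transition (default ρ_bg = 0). A planted fraction of
genes (default 5%) gains a fixed log2 fold change (default 2.0, i.e.
4-fold) at timepoints after the tipping time; controls always stay at
baseline. Count mode maps each log2 value m through 2^m into a
negative-binomial draw with dispersion φ (variance μ + φμ²,
default φ = 0.05). One `numpy` generator seeded from the design's seed
drives everything; generation is vectorised and single-threaded, gene
labels are cosmetic, and identical seeds give byte-identical output.

What the generator does *not* emulate: library-size and batch effects,
mean–variance coupling on the log scale, heavy-tailed expression,
gene–gene correlation beyond one module factor plus one global factor,
and gradual (rather than single-timepoint) transitions. Passing
recovery tests on this generator therefore demonstrates correctness of
the statistics and the machinery under the assumed model, not
performance on real transcriptomes.

Companion generators emit interaction networks (prescribed links from
module genes to planted differential genes plus random noise edges) and
GMT gene-set collections with prescribed per-gene membership
multiplicities, so that expected linked-DEG counts and pathway-count
rankings are known by construction.

## Detection ceiling at five replicates

With r = 5 the realized strength of the planted module varies widely
between datasets: the shared factor is sampled only five times, so its
sample variance is χ²₄/4-distributed, and the module's realized CI at
the tipping time has median ≈ 1.6 with interquartile range ≈ [1.0, 2.2]
(60-seed measurement at the default design). The dominant-group CI at a
*non*-tipping timepoint — the maximum over thousands of candidate
clusters of optimised selection noise — concentrates tightly at
1.50–1.57. Roughly half of all realizations of the default design
therefore produce a module that no selection-consistent procedure can
distinguish from noise; the pipeline detects ≈ 40–50% of them
(honest no-calls otherwise), and when it does call the tipping point the
recovered module matches the planted one at Jaccard 0.69–0.87 with
permutation p ≈ 0.005. This is an identifiability limit of the design
(five replicates, variance inflation 3), not of the estimator; power
rises steeply with replicates, module size or variance inflation, as the
strong-effect configurations used in the wiring tests show.

## Differential expression stand-in

The DEG stage is deliberately simple plumbing: per-gene Welch t-test on
log2 values with Benjamini–Hochberg FDR control, pass rule
|log2FC| > 1 AND q < 0.05 (fold change > 2 or < 0.5). It is not a
count-based NB-GLM; externally produced DEG tables can be imported and
used in its place everywhere downstream. The post- vs pre-tipping
contrast pools treated samples strictly after vs strictly before the
tipping timepoint, excluding the tipping samples themselves so the
unstable critical state contaminates neither side. Calibration under
the generator's Gaussian log-scale model: null type-I rate 0.05 ± 0.015
and recall ≥ 0.95 for 8-fold shifts at n = 5 per group.

## Ranking and enrichment

Over-representation of a query gene list in a gene set uses the
one-sided hypergeometric upper tail (Fisher's exact test), BH-adjusted
across a collection. DNB genes are ranked by `pathway_count` — the
total number of supplied fibrosis-associated sets containing the gene,
summed across collections (a `union` mode counting unique set ids is
available) — with ties broken by the number of differentially expressed
direct neighbours in the interaction network, then gene id. The summed
count reproduces the published ordering of the twelve key fibrosis
genes (Tgfb3 first with 4 + 5 = 9); those published per-gene counts ship
as data constants from which GMT-style fixtures are rebuilt at run time.

## Toggle-switch model

The two-gene mutual-repression system

    dx/dt = α₁/(1 + y^β₁) − x,   dy/dt = α₂/(1 + x^β₂) − y

is dimensionless; α are effective synthesis rates, β cooperativity
exponents, and degradation is normalised to rate 1. Defaults
α₁ = α₂ = 3, β₁ = β₂ = 2 sit robustly inside the bistable regime (the
motivating study states only that parameters were chosen in plausible
ranges). Fixed points are found by 1-D reduction — any equilibrium
satisfies y = α₂/(1 + x^β₂) and x = α₁/(1 + y^β₁) ≤ α₁ — with a dense
mixed log/linear bracket scan of x ∈ (0, α₁] refined by bisection to
1e-12; the analytic Jacobian classifies each root (stable node, saddle,
other). In the symmetric case the fixed point x = y = s solves
s(1 + s^β) = α and destabilises through a pitchfork when the loop gain
β·s^β/(1 + s^β) exceeds 1, i.e. at s_c = (β − 1)^(−1/β) and
α_c = s_c·β/(β − 1): exactly 2 at β = 2, ≈ 1.1906 at β = 3, and no
bifurcation for β ≤ 1. The numeric `bifurcation_scan` (stable-count
flip located by bisection to 1e-4) and this closed form agree across a
(β, α) grid and serve as mutual cross-checks.

Trajectories integrate with adaptive RK45 (rtol 1e-9); convergence means
the rate norm falls below 1e-8, and non-convergence is an error unless
explicitly tolerated. Basin maps assign each grid start to the stable
node it reaches (match tolerance 1e-4); the basin boundary is the
saddle's stable manifold — the diagonal in the symmetric case. The
stochastic variant is Euler–Maruyama with additive noise, reflection at
zero, and a step-size guard dt ≤ 0.2 (the deterministic relaxation rate
is 1); it exhibits critical slowing down: stationary variance grows as α
approaches the pitchfork from below, because the soft eigenvalue
−1 + β·s^β/(1 + s^β) → 0.

## Pipeline and reproducibility

`run_pipeline` executes simulate → DNB → DEG → rank → toggle from a
single validated config (unknown keys are errors). One top-level seed
expands through `numpy.random.SeedSequence` into independent per-stage
seeds (all below 2³¹); every active tunable is logged, the report embeds
the config hash and seeds, and re-running the same config reproduces the
report exactly. The acceptance script (`scripts/acceptance.py`)
recomputes all headline quantities with 50 simulation seeds for the
recovery and null-calibration rates, 20 seeds for DEG calibration and
the stochastic-toggle variance vote — sizes chosen so the full run
completes in roughly ten minutes on one CPU while keeping Monte-Carlo
error a few percent.

## Known limitations

- The dominant-group discovery is a reconstruction; the original DNB
  publications leave the algorithm to earlier references that describe
  it only loosely.
- PCC_o uses all outside genes; no network-restricted variant.
- The permutation null assumes exchangeability of replicate blocks
  across timepoints per gene; strong time trends in variance under the
  null would be scored as signal.
- Balanced designs get the block-constrained permutation; unbalanced
  designs fall back to the unconstrained per-gene shuffle with its
  outlier-coincidence liability.
- No single-sample DNB variants, no landscape/potential estimation, no
  parameter fitting of the toggle model to expression data.
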