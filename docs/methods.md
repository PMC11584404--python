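# Methods

## Deconvolution model

Each spot `s` with library size `N_s` is modelled as a multinomial mixture
of cell-type expression profiles,

    x_s ~ Multinomial(N_s, Σ_k θ_sk φ_k),    θ_s ~ Dirichlet(α·1),

where `φ_k` is the type-`k` expression fraction vector over the gene panel
and `θ_s` the spot's cell-type fractions. The panel is the union of per-type
marker genes: for every fine type, pairwise Welch t-tests on
log2(library-normalized/10⁴ + 1) expression against the other types, keeping
genes with maximum p < 0.01 and minimum log2 fold change > 0.1 across the
required comparisons. Fine types whose coarse label is `tumor` are compared
only against non-tumor types, so a gene shared by all tumor subtypes is
retained rather than discarded for failing tumor-vs-tumor contrasts.
Profiles are per-type pooled counts over the panel normalized to sum 1;
`pseudo_min` (default 0, maximal contrast) floors the normalized entries and
renormalizes.

Inference is a conjugate Gibbs sampler: (i) given `θ_s`, each gene's count
is allocated to types with multinomial probability ∝ `θ_sk φ_kg`; (ii) given
the allocations, `θ_s ~ Dirichlet(α + n_s·)`. Defaults: flat prior α = 1,
chain length 1,000, burn-in 500, thinning 2 (250 retained draws); genes
expressed in fewer than 4 spots are dropped first. Posterior means of `θ`
and of the allocation array `Z` are returned; allocation conserves counts,
so `Σ_k Z_skg = x_sg` to machine precision. Zero-count spots get the prior
mean and are flagged. An optional second pass (`refine_types=...`)
re-estimates selected type profiles from their pooled allocated counts and
reruns the sampler — a coarse guard against platform differences between
reference and spots; it is off by default and not used by the pipeline.

The spot-level expression of a type subset (the tumor matrix) is the
ceiling of the summed posterior-mean allocations. Rounding up keeps the
matrix integer for count-based nulls; at shallow depth it audibly inflates
near-zero allocations (every gene with any tiny tumor allocation gains one
count), which is why validation of allocation accuracy is done on the
pre-rounding means.

Correctness is checked two ways: an exhaustive-enumeration posterior (sum
over all allocation tables, tractable for spot totals ≤ 8 and ≤ 3 types)
that shares no code with the sampler, and a closed-form Dirichlet posterior
in the disjoint-support limit.

## Spatial statistics

Spots form a per-sample Euclidean k-nearest-neighbor graph (k = 6),
symmetrized by union, all weights 1; cross-sample edges are impossible by
construction and multi-sample datasets are offset in coordinates so spots
never overlap. Counts are standardized against a depth-adjusted
negative-binomial null: gene proportion `p_g` from pooled counts, null mean
`μ_gi = p_g N_i`, variance `μ(1 + α_g μ)` with per-gene dispersion `α_g ≥ 0`
by method of moments (floored at 0; zero-variance entries yield residual 0).

The autocorrelation statistic is the edge sum of residual products,
`H_g = Σ_{(i,j)∈E} w_ij x̃_gi x̃_gj`, each unordered pair once. Because the
fitted null forces each gene's residual sum toward 0, the exchangeability
(permutation) null mean of `H` is not exactly 0 but
`Σw² ((Σr)² − Σr²)/(n(n−1)) ≈ −Σw²/(n−1)`; z-scores standardize `H` minus
this exact mean by `√(Σw²)`. Without the centering every null z carries a
`−√(Σw²)/(n−1)` offset (≈ −0.1 at 300 spots), which distorts calibration;
with it, permuted data give z with mean ≈ 0 and variance ≈ 1. Two-sided
normal p-values are BH-adjusted; genes at FDR < 0.01 enter the module
stage.

The cross-gene statistic is
`C_gh = Σ_{(i,j)∈E} w_ij (x̃_gi x̃_hj + x̃_hi x̃_gj)/2`. Under independence
the two half-weighted products per edge are uncorrelated, so
`Var[C_gh] = Σw²/2` for `g ≠ h` — validated against permutation — while the
diagonal reduces to `H_g` with variance `Σw²`; each entry is standardized by
its own null variance, making the diagonal equal the autocorrelation z.

Modules are built bottom-up: clusters start as singletons and the pair with
the highest average cross-pair z merges while that linkage stays above the z
cutoff at which a pair's one-sided BH-adjusted p falls below the module FDR
(0.05). Ties break on the lexicographically smallest gene-index pair, making
the procedure deterministic. Clusters below the 15-gene floor stay
unassigned (−1) under `core_only`. Average linkage was chosen over
single/complete linkage for robustness to single spurious pairs; it is a
parameter of the implementation, not a claim about the reference software's
internals. Module scores are the mean standardized residual over member
genes, optionally smoothed by averaging over each spot and its neighbors.

## Pipeline and consensus

The full pipeline: marker selection → reference profile → spot QC →
deconvolution → tumor matrix → KNN graph → autocorrelation (FDR < 0.01) →
pairwise z → modules. Spot QC uses the production floors of 1,000 detected
genes and 1,000 UMIs; for datasets shallower than the floors the effective
threshold is `min(configured, 0.25 × median)` with a logged notice, so the
same configuration runs on full-scale and scaled-down data without silently
discarding everything. The raw-count baseline (`use_deconvolution=False`)
runs the identical spatial analysis on raw counts over the same gene panel.

The consensus procedure thins the raw counts binomially at rate 0.6 and
reruns the entire pipeline (including deconvolution) 100 times by default.
A gene's consensus score is the average, across reruns, of the fraction of
its full-data module co-members assigned to the same module as the gene in
that rerun; a gene unassigned in a rerun contributes 0 for it, penalizing
instability. Scoring by co-membership makes the score invariant to module
relabeling. Genes with score ≥ 0.8 are retained and final modules are refit
on the retained genes from the full-data pairwise z. Replicates use
independent child seeds of one root seed, so results are identical
regardless of execution order; failed replicates are recorded and excluded
from the average.

## Benchmark

Coarse-type marker sets (tumor plus each non-tumor type) come from pairwise
Welch t-tests between coarse groups at the same thresholds, ranked by
minimum log2 fold change, top 100 per set, de-duplicated by best fold
change. Autocorrelation z-scores of the deconvolved and raw arms are
compared per set by one-sided paired t-tests: for tumor sets the
alternative is "deconvolved > raw", for non-tumor sets the opposite.
Pairwise |z| values are compared the same way over the three pair
categories (tumor–tumor expects a gain; tumor–nontumor and
nontumor–nontumor expect a loss). Genes (or pairs) missing from either arm
are excluded pairwise; categories with fewer than 3 pairs report an
undefined p. The bulk contrast computes per gene
`log2((mean_A + 1)/(mean_B + 1))` on expression values as provided plus a
two-sided rank-sum p between groups, and per module a two-sided Wilcoxon
signed-rank of member log2FCs against 0 (a member-vs-rest rank-sum variant
is available behind `module_test="vs_rest"`; neither is asserted to be the
canonical choice).

## Synthetic data: what it emulates, and what it does not

The generator draws K = 6 cell types (2 tumor, 4 non-tumor) over a 15×14
lattice (210 spots), 400 genes with log-normal baseline rates, 10 markers
per type at 20× enrichment, and library sizes log-normal around 2,000 UMIs
(σ = 0.35) — a deliberately scaled-down Visium tissue that keeps every
validation run on one CPU in minutes. The reference draws 200 cells/type
with gamma-Poisson noise (dispersion 0.15) at ~3,000 counts/cell.

Cell-type fractions are a softmax of Gaussian-bump logit fields plus
independent per-spot logit jitter (σ = 0.6): the bumps emulate
histology-scale regions, the jitter the cell-sampling noise of which mix a
55-µm spot happens to capture. The jitter is measurement-level — technical
replicates redraw it while the translated smooth fields are shared.

Two 20-gene modules are planted in genes 15× enriched in both tumor types
(emulating tumor-specific transcription-factor programs); their expression
is multiplied by `1 + amplitude·field(s)` (amplitude 2.5, Gaussian bump
fields) in the tumor profiles only, then renormalized. Tumor-fraction bumps
are deliberately offset from the module bumps — tumor programs vary within
tumor regions rather than tracking tumor abundance — while non-tumor
infiltration colocalizes with the tumor niches: the designated confounder
type sits on module 0's bump and the last non-tumor type on module 1's.
This is the regime the method exists for, and it is also the regime where
the deconvolved-vs-raw comparison is informative: exploratory sizing showed
that with weakly tumor-enriched module genes, or with non-tumor fields that
are as smooth as everything else and nowhere colocalized, the raw arm
*gains* autocorrelation from the fraction field itself and deconvolution
has nothing to remove. Passing benchmarks on this tissue therefore
demonstrate the confounded-mixture case, not a universal superiority of
deconvolved analysis.

Other simplifications relative to real Visium data: no platform/batch
effect between reference and spots (the reference profiles are the true
generative profiles up to sampling noise), no spatial covariance structure
beyond Gaussian bumps, no segmentation/histology artifacts, no
ambient-RNA contamination, and hexagonal geometry replaced by a square
lattice (the statistics only consume the KNN graph, which is
geometry-agnostic).

## Numerical choices and degenerate inputs

- One root seed; fixed child streams per operation
  (`rates/reference/spatial/thin/replicate`), so components reproduce
  independently of call order; integer draws are bit-identical across runs.
- Marker tests: Welch (unequal variance); identical groups give p = 1, not
  NaN. Types with < 2 cells are excluded with a warning.
- Deconvolution: all-zero profile columns are an error; underflowing
  allocation rows fall back to uniform over types with φ > 0; zero-count
  spots get the prior mean.
- Graph: samples with ≤ k spots use a reduced k (warning); single-spot
  samples stay isolated (warning).
- Concordance: zero-variance vectors give r = NaN ("undefined"), never an
  exception; regions missing from one replicate are dropped with a warning.
- Dispersion is floored at 0; residuals with zero null variance are set
  to 0.
- Problem sizes in tests and in `scripts/acceptance.py` (210–300 spots,
  400–500 genes, 20 consensus reruns instead of 100) are the package's
  validation scale, chosen so the whole suite runs on one CPU in minutes;
  all thresholds and statistical conclusions are computed at those sizes.

## Known limitations

- The NB null is fitted per gene on the same data it standardizes, so
  strongly structured genes are conservatively shrunk (their dispersion
  absorbs signal variance); this is intrinsic to the moment-matched design.
- Posterior-mean tumor counts are smoother than a multinomial realization
  of the same totals; the NB null floors dispersion at Poisson, so z-scores
  on deconvolved counts are mildly conservative.
- The ceiling on tumor counts inflates near-zero allocations at shallow
  depth (see above).
- Consensus scores are interpreted relative to the full-data modules; a
  genuinely different but stable module structure in subsampled data would
  be penalized.
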