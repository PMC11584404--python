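# prismspot

Deconvolution-aware discovery of spatial gene-expression modules in
spot-based spatial transcriptomics.

## The problem

A Visium spot (~55 µm) captures transcripts from several cells, so spatial
co-expression computed on raw spot counts confounds two very different
signals: genes co-regulated *within* a cell type of interest, and genes that
merely belong to cell types that *colocalize*. In tumors with mixed
histology — e.g. prostate adenocarcinoma (PRAD) transitioning to
neuroendocrine prostate cancer (NEPC) — this makes it hard to tell whether a
transcription-factor module marks a tumor cell state or a stromal/immune
neighborhood.

`prismspot` addresses this by combining two steps:

1. **Bayesian deconvolution.** Each spot's counts are modelled as a
   multinomial mixture of cell-type expression profiles built from a
   labelled single-cell/nucleus reference:

       x_s ~ Multinomial(N_s, Σ_k θ_sk φ_k),    θ_s ~ Dirichlet(α)

   A conjugate Gibbs sampler alternates between allocating each gene's
   counts to cell types (probability ∝ θ_sk φ_kg) and redrawing θ_s. The
   posterior means give cell-type fractions θ (the μ of the mixture) and a
   cell-type-specific count matrix Z (U), with Σ_k Z_skg = x_sg exactly.
   The spot-level tumor expression matrix is ⌈Σ_{k∈tumor} Z_skg⌉.

2. **Graph-based spatial statistics on the tumor counts.** On a k-nearest-
   neighbor spot graph (k = 6, equal weights, neighborhoods restricted
   within each sample), counts are standardized against a depth-adjusted
   negative-binomial null (mean p_g·N_i, variance μ(1+α_g μ), dispersion by
   method of moments) and scored by

       H_g = Σ_{(i,j)∈E} x̃_gi x̃_gj,   z_g = (H_g − E_perm[H_g]) / √(Σ w²)

   with the analogous cross-gene statistic feeding a bottom-up merging of
   genes into spatial modules (autocorrelation FDR < 0.01, module FDR
   0.05, ≥ 15 genes per module). A read-subsampling consensus (60 % binomial
   thinning, 100 reruns by default) scores how stably each gene keeps its
   module company; genes with consensus ≥ 0.8 are retained.

A synthetic-data module generates references and tissues with known
fractions, planted spatially coherent tumor modules and a colocalized
non-tumor confounder, so every stage can be validated against ground truth,
and a benchmark module quantifies the signal-to-noise gain of deconvolved
over raw analysis with one-sided paired t-tests.

## Worked example

```python
import prismspot as ps

cfg = ps.SimConfig()                      # 210 spots, 6 types, 2 planted modules
ref = ps.make_reference(cfg)              # labelled single-cell reference
spots, truth = ps.make_spatial_dataset(cfg)

model = ps.PrismSpotModel(spots, ref)     # markers + profiles + pipeline
result = model.fit(seed=1)
print(result.summary())
```

prints (numbers from this exact seed):

```
PrismSpot
  spots kept: 210/210 (QC floors: 86 genes, 454 UMIs)
  gene panel: 101 markers; analyzed: 101
Spatial co-expression analysis (KNN graph, NB null)
  spots: 210   genes tested: 101   edges: 764 (k=6)
  significant autocorrelation (FDR < 0.01): 60
  modules (>= 15 genes): 2
    module 0: 20 genes (mod0_g0, mod0_g1, mod0_g2, mod0_g3, mod0_g4, ...)
    module 1: 20 genes (mod1_g0, mod1_g1, mod1_g2, mod1_g3, mod1_g4, ...)
```

i.e. all 210 spots pass the (auto-scaled) QC floors, the marker union forms
a 101-gene deconvolution panel, 60 genes show significant spatial
autocorrelation in the tumor-specific counts, and the two recovered
20-gene modules are exactly the two planted tumor programs. Fractions,
module scores and consensus follow the same pattern:

```python
result.theta                              # spot x type posterior fractions
result.module_scores()                    # smoothed per-spot module scores
cons = ps.consensus_modules(model, full_result=result, n_rep=20, seed=1)
```

A command-line interface mirrors the library:

```bash
prismspot simulate --out demo/sim
prismspot deconvolve --spots demo/sim/spatial --ref demo/sim/reference --out demo/dec
prismspot modules --counts demo/dec/tumor_counts --coords demo/sim/spatial/coordinates.tsv --out demo/mods
prismspot run-all --out demo/full --reps 10 --seed 7
```

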