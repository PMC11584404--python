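"""The PrismSpot pipeline: deconvolution-aware spatial module discovery.

Visium-style spots mix several cell types, so spatial co-expression found on
raw counts confounds tumor-intrinsic programs with cell-type colocalization.
The pipeline therefore (1) selects cell-type markers from a single-cell
reference, (2) deconvolves each spot by Gibbs sampling into cell-type
fractions and cell-type-specific counts, (3) rounds up the counts allocated
to the tumor types, and (4) runs the graph-based autocorrelation/module
analysis on that tumor-specific matrix, with neighborhoods restricted within
samples. A read-subsampling consensus procedure scores how stably each gene
keeps its module company under 60% binomial thinning.

``use_deconvolution=False`` runs the identical spatial analysis on raw
counts (the "standard" un-deconvolved baseline used for benchmarking).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .datasets import SpatialDataset
from .deconvolution import (
    DeconvolutionResults,
    GibbsConfig,
    MarkerSelection,
    MixtureDeconvolution,
    build_reference,
    select_markers,
    tumor_expression,
)
from .simulate import ReferenceData, binomial_thin
from .spatial import ModuleSet, SpatialCoexpression, extract_modules

logger = logging.getLogger("prismspot")

__all__ = [
    "PrismSpotModel",
    "PrismSpotResults",
    "ConsensusResult",
    "run_prismspot",
    "consensus_modules",
]


def _effective_threshold(configured: int, values: np.ndarray, label: str) -> int:
    """Scale a spot-QC floor down for datasets shallower than the configured
    value: the effective floor is min(configured, 0.25 * median)."""
    med = float(np.median(values))
    eff = int(min(configured, max(1, np.floor(0.25 * med))))
    if eff < configured:
        logger.info(
            "spot QC threshold for %s scaled from %d to %d (median %.0f)",
            label, configured, eff, med,
        )
    return eff


@dataclass
class FilterReport:
    """Spot-QC bookkeeping: effective thresholds and per-criterion failures."""

    min_genes: int
    min_umis: int
    failed_genes: int
    failed_umis: int
    n_kept: int
    n_total: int


class PrismSpotResults:
    """Everything the pipeline computed for one dataset.

    Attributes
    ----------
    deconvolution : DeconvolutionResults or None
        ``None`` for the raw (un-deconvolved) baseline.
    analysis_counts : pandas.DataFrame
        Spot-by-gene matrix the spatial statistics ran on (tumor-specific
        counts, or raw counts in baseline mode).
    coexpression : SpatialCoexpressionResults
    """

    def __init__(self, model, deconvolution, analysis_counts, coexpression,
                 filter_report, spots_used):
        self.model = model
        self.deconvolution = deconvolution
        self.analysis_counts = analysis_counts
        self.coexpression = coexpression
        self.filter_report = filter_report
        self.spots_used = spots_used

    @property
    def autocorrelation(self) -> pd.DataFrame:
        return self.coexpression.autocorrelation

    @property
    def modules(self) -> ModuleSet:
        return self.coexpression.modules

    @property
    def theta(self) -> pd.DataFrame | None:
        return None if self.deconvolution is None else self.deconvolution.theta

    def module_scores(self, smoothed: bool = True) -> pd.DataFrame:
        return self.coexpression.module_scores(smoothed=smoothed)

    def pairwise_z_for(self, genes) -> pd.DataFrame:
        """Pairwise local-correlation z for an arbitrary gene list (e.g.
        benchmark marker sets), bypassing the autocorrelation FDR filter;
        genes absent from the analysis matrix are dropped."""
        from .spatial import pairwise_local_correlation

        cm = self.coexpression.model
        present = pd.Index([g for g in genes if g in cm.genes])
        return pairwise_local_correlation(cm.counts, cm.graph, cm.null,
                                          genes=present)

    def plot_module_scores(self, smoothed: bool = True, axes=None):
        """Scatter the per-spot module scores on the spot coordinates."""
        import matplotlib.pyplot as plt

        scores = self.module_scores(smoothed=smoothed)
        coords = self.model.spots.coords[self.spots_used]
        n = scores.shape[1]
        if axes is None:
            _, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
            axes = axes[0]
        for ax, col in zip(axes, scores.columns):
            sc = ax.scatter(coords[:, 1], -coords[:, 0], c=scores[col], s=18,
                            cmap="viridis")
            ax.set_title(col)
            ax.set_aspect("equal")
            plt.colorbar(sc, ax=ax)
        return axes

    def summary(self) -> str:
        fr = self.filter_report
        head = [
            "PrismSpot" if self.deconvolution is not None else
            "Raw-count spatial analysis (no deconvolution)",
            f"  spots kept: {fr.n_kept}/{fr.n_total} "
            f"(QC floors: {fr.min_genes} genes, {fr.min_umis} UMIs)",
            f"  gene panel: {len(self.model.panel)} markers; analyzed: "
            f"{self.analysis_counts.shape[1]}",
        ]
        return "\n".join(head) + "\n" + self.coexpression.summary()


class PrismSpotModel:
    """Ties a spatial dataset to a single-cell reference.

    Parameters
    ----------
    spots
        Spot counts with coordinates and sample ids; one analysis is run
        across all samples with sample-restricted neighborhoods.
    reference
        Labelled single-cell reference used for markers and profiles.
    tumor_types
        Fine types whose allocated counts form the analysis matrix; defaults
        to every fine type whose coarse label is ``"tumor"``.
    extra_genes
        Genes appended to the marker-union panel (e.g. a transcription-factor
        list of interest).
    use_deconvolution
        ``False`` runs the same spatial analysis on raw counts.
    """

    def __init__(
        self,
        spots: SpatialDataset,
        reference: ReferenceData,
        tumor_types: Sequence[str] | None = None,
        config: RunConfig | None = None,
        extra_genes: Sequence[str] | None = None,
        use_deconvolution: bool = True,
    ):
        self.spots = spots
        self.reference = reference
        self.config = config or RunConfig()
        self.use_deconvolution = use_deconvolution

        if tumor_types is None:
            coarse = reference.coarse_labels or {}
            tumor_types = [t for t in pd.unique(reference.labels)
                           if coarse.get(t) == "tumor"]
        if use_deconvolution and not tumor_types:
            raise ValueError("no tumor types given and none labelled 'tumor'")
        self.tumor_types = list(tumor_types)

        cfg = self.config
        self.markers: MarkerSelection = select_markers(
            reference,
            p_threshold=cfg.marker_p_threshold,
            fc_threshold=cfg.marker_fc_threshold,
        )
        panel = list(self.markers.union)
        for g in extra_genes or []:
            if g not in panel:
                panel.append(g)
        panel = [g for g in panel if g in spots.genes]
        if not panel:
            raise ValueError("empty gene panel after intersecting with spots")
        self.panel = pd.Index(panel, name="gene")
        self.profile = build_reference(reference, self.panel, pseudo_min=cfg.pseudo_min)

    # -- spot QC -------------------------------------------------------------
    def _qc(self, dataset: SpatialDataset) -> tuple[SpatialDataset, FilterReport, np.ndarray]:
        cfg = self.config
        umis = dataset.library_sizes()
        ngenes = dataset.genes_detected()
        min_umis = _effective_threshold(cfg.min_umis_per_spot, umis, "UMIs")
        min_genes = _effective_threshold(cfg.min_genes_per_spot, ngenes, "genes")
        ok = (umis >= min_umis) & (ngenes >= min_genes)
        report = FilterReport(
            min_genes=min_genes,
            min_umis=min_umis,
            failed_genes=int((ngenes < min_genes).sum()),
            failed_umis=int((umis < min_umis).sum()),
            n_kept=int(ok.sum()),
            n_total=len(ok),
        )
        if not ok.any():
            raise ValueError(
                f"all {report.n_total} spots filtered out "
                f"({report.failed_genes} below {min_genes} genes, "
                f"{report.failed_umis} below {min_umis} UMIs)"
            )
        return dataset.subset_spots(ok), report, np.flatnonzero(ok)

    # -- fitting -------------------------------------------------------------
    def fit(self, seed: int | None = None) -> PrismSpotResults:
        return self._fit_on(self.spots, seed=seed)

    def _fit_on(self, dataset: SpatialDataset, seed: int | None) -> PrismSpotResults:
        cfg = self.config
        data, report, kept = self._qc(dataset)

        decon: DeconvolutionResults | None = None
        if self.use_deconvolution:
            gibbs = GibbsConfig(
                alpha=cfg.alpha,
                chain_length=cfg.chain_length,
                burn_in=cfg.burn_in,
                thinning=cfg.thinning,
                seed=cfg.seed if seed is None else seed,
            )
            model = MixtureDeconvolution(
                data, self.profile, config=gibbs,
                min_spots_per_gene=cfg.min_spots_per_gene,
            )
            decon = model.fit()
            counts = tumor_expression(decon, self.tumor_types)
        else:
            sub = data.subset_genes(self.panel)
            expressed = np.asarray((sub.counts > 0).sum(axis=0)).ravel()
            keep = expressed >= cfg.min_spots_per_gene
            counts = pd.DataFrame(
                np.asarray(sub.counts[:, np.flatnonzero(keep)].todense()),
                index=data.spots, columns=self.panel[keep],
            )

        nonzero = counts.to_numpy().sum(axis=0) > 0
        counts = counts.loc[:, nonzero]
        if counts.shape[1] == 0:
            raise ValueError("no gene left with nonzero analysis counts")

        coex = SpatialCoexpression(
            counts.to_numpy(),
            coords=data.coords,
            sample_ids=data.sample_ids,
            genes=counts.columns,
            spot_names=list(data.spots),
            k=cfg.k_neighbors,
            autocorr_fdr=cfg.autocorr_fdr,
            module_fdr=cfg.module_fdr,
            min_gene_threshold=cfg.min_gene_threshold,
            core_only=cfg.core_only,
        ).fit()
        return PrismSpotResults(self, decon, counts, coex, report, kept)


def run_prismspot(
    spots: SpatialDataset,
    reference: ReferenceData,
    tumor_types: Sequence[str] | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra_genes: Sequence[str] | None = None,
    use_deconvolution: bool = True,
) -> PrismSpotResults:
    """One-call pipeline: deconvolve, extract tumor counts, find modules."""
    return PrismSpotModel(
        spots, reference, tumor_types=tumor_types, config=config,
        extra_genes=extra_genes, use_deconvolution=use_deconvolution,
    ).fit(seed=seed)


# ---------------------------------------------------------------------------
# consensus over read subsampling
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    """Per-gene stability of module co-membership under read subsampling.

    A gene's consensus score is the average, over subsampled reruns, of the
    fraction of its full-data module co-members that land in the same module
    as the gene in that rerun; an unassigned gene contributes 0 for that
    rerun. Scores are invariant to module relabeling by construction.
    """

    scores: pd.Series
    retained: pd.Index
    final_modules: ModuleSet
    replicate_assignments: pd.DataFrame
    n_success: int
    n_requested: int
    rate: float
    threshold: float
    failures: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Subsampling consensus",
            f"  replicates: {self.n_success}/{self.n_requested} at rate "
            f"{self.rate:g}; threshold {self.threshold:g}",
            f"  retained genes: {len(self.retained)}/{len(self.scores)}",
            f"  final modules: {self.final_modules.n_modules}",
        ]
        return "\n".join(lines)


def consensus_modules(
    model: PrismSpotModel,
    full_result: PrismSpotResults | None = None,
    rate: float | None = None,
    n_rep: int | None = None,
    threshold: float | None = None,
    seed: int | None = None,
) -> ConsensusResult:
    """Score module stability by rerunning the pipeline on thinned reads.

    Raw spot counts are binomially thinned at ``rate`` before every rerun, so
    each replicate re-deconvolves from scratch; replicates are independent
    given their child seeds and the result does not depend on execution
    order.
    """
    cfg = model.config
    rate = cfg.subsample_rate if rate is None else rate
    n_rep = cfg.n_subsamples if n_rep is None else n_rep
    threshold = cfg.consensus_threshold if threshold is None else threshold
    seed = cfg.seed if seed is None else seed
    if n_rep < 2:
        raise ValueError("consensus needs at least 2 replicates")

    if full_result is None:
        full_result = model.fit(seed=seed)
    full_assign = full_result.modules.assignments
    module_genes = full_assign.index[full_assign >= 0]
    if len(module_genes) == 0:
        raise ValueError("no full-data module genes to score")
    comembers = {
        g: [h for h in module_genes if h != g
            and full_assign[h] == full_assign[g]]
        for g in module_genes
    }

    ss = np.random.SeedSequence([int(seed) % (2**31), 977])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_rep)]

    rep_assign = pd.DataFrame(
        -1, index=module_genes, columns=[f"rep{r}" for r in range(n_rep)],
        dtype=int,
    )
    per_rep_scores = []
    failures: list[str] = []
    for r, s in enumerate(child_seeds):
        try:
            thinned = binomial_thin(model.spots, rate, seed=s)
            res = model._fit_on(thinned, seed=s + 1)
        except Exception as exc:  # noqa: BLE001 - replicate failures are recorded
            warnings.warn(f"replicate {r} failed: {exc}")
            failures.append(f"rep{r}: {exc}")
            per_rep_scores.append(None)
            continue
        a = res.modules.assignments
        aligned = a.reindex(module_genes, fill_value=-1)
        rep_assign.iloc[:, r] = aligned.to_numpy()
        sc = {}
        for g in module_genes:
            mg = aligned[g]
            if mg < 0 or not comembers[g]:
                sc[g] = 0.0 if comembers[g] else float(mg >= 0)
            else:
                same = sum(aligned[h] == mg for h in comembers[g])
                sc[g] = same / len(comembers[g])
        per_rep_scores.append(pd.Series(sc))

    ok = [s for s in per_rep_scores if s is not None]
    if not ok:
        raise RuntimeError("every consensus replicate failed")
    scores = pd.concat(ok, axis=1).mean(axis=1)
    scores.index.name = "gene"
    retained = scores.index[scores >= threshold]

    if len(retained) > 0:
        final = extract_modules(
            full_result.coexpression.pairwise_z.loc[retained, retained],
            min_gene_threshold=cfg.min_gene_threshold,
            fdr_threshold=cfg.module_fdr,
            core_only=cfg.core_only,
        )
    else:
        final = ModuleSet(
            assignments=pd.Series(dtype=int),
            pairwise_z=pd.DataFrame(),
            min_gene_threshold=cfg.min_gene_threshold,
            fdr_threshold=cfg.module_fdr,
        )
    return ConsensusResult(
        scores=scores,
        retained=retained,
        final_modules=final,
        replicate_assignments=rep_assign,
        n_success=len(ok),
        n_requested=n_rep,
        rate=rate,
        threshold=threshold,
        failures=failures,
    )
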