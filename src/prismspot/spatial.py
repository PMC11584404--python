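"""Graph-based spatial autocorrelation and co-expression modules for counts.

Counts on a k-nearest-neighbor spot graph are standardized against a
depth-adjusted negative-binomial null: gene ``g`` at spot ``i`` has null mean
``mu_gi = p_g * N_i`` (``p_g`` the gene's overall proportion, ``N_i`` the
spot depth) and variance ``mu_gi * (1 + a_g * mu_gi)`` with per-gene
dispersion ``a_g >= 0`` fitted by the method of moments. The autocorrelation
statistic is the sum of products of standardized residuals over graph edges,

    H_g = sum_{(i,j) in E} w_ij * x~_gi * x~_gj,

with each unordered pair counted once; under the independence null
``E[H] = 0`` and ``Var[H] = sum w_ij^2``, giving a z-score and a
Benjamini-Hochberg FDR. The cross-gene analogue drives a bottom-up merging of
genes into spatial co-expression modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpatialGraph",
    "NullModel",
    "ModuleSet",
    "build_knn_graph",
    "fit_null_model",
    "local_autocorrelation",
    "pairwise_local_correlation",
    "extract_modules",
    "module_scores",
    "SpatialCoexpression",
    "SpatialCoexpressionResults",
]


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------


@dataclass
class SpatialGraph:
    """Symmetric KNN edge list; neighborhoods never cross samples.

    ``edges`` holds each unordered pair once (i < j); all weights are 1.
    """

    n_nodes: int
    edges: np.ndarray  # (E, 2) int, i < j
    weights: np.ndarray  # (E,)
    sample_ids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights disagree")
        if len(self.edges) and (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValueError("edges must be stored with i < j")
        s = np.asarray(self.sample_ids)
        if len(self.edges) and (s[self.edges[:, 0]] != s[self.edges[:, 1]]).any():
            raise ValueError("edge joins spots of different samples")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def sum_w2(self) -> float:
        return float((self.weights**2).sum())

    def adjacency(self) -> sparse.csr_matrix:
        """Full symmetric 0/1 adjacency (both directions)."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = np.concatenate([self.weights, self.weights])
        return sparse.csr_matrix(
            (w, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        np.add.at(d, self.edges.ravel(), 1)
        return d


def build_knn_graph(
    coords: np.ndarray, sample_ids: np.ndarray | None = None, k: int = 6
) -> SpatialGraph:
    """Per-sample Euclidean k-nearest-neighbor graph, symmetrized by union.

    Samples with at most ``k`` spots use a reduced ``k`` (with a warning);
    cross-sample edges are impossible by construction.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if sample_ids is None:
        sample_ids = np.repeat("S1", n)
    sample_ids = np.asarray(sample_ids)

    pairs: set[tuple[int, int]] = set()
    for s in pd.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == s)
        if len(idx) == 1:
            warnings.warn(f"sample {s!r} has a single spot; it stays isolated")
            continue
        k_s = k
        if len(idx) <= k:
            k_s = len(idx) - 1
            warnings.warn(
                f"sample {s!r} has {len(idx)} spots <= k={k}; using k={k_s}"
            )
        nn = NearestNeighbors(n_neighbors=k_s + 1).fit(coords[idx])
        _, nbrs = nn.kneighbors(coords[idx])
        for a, row in zip(idx, nbrs):
            for b_local in row[1:]:
                b = idx[b_local]
                pairs.add((min(a, b), max(a, b)))
    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    return SpatialGraph(
        n_nodes=n,
        edges=edges,
        weights=np.ones(len(edges)),
        sample_ids=sample_ids,
        k=k,
    )


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


@dataclass
class NullModel:
    """Depth-adjusted negative-binomial null per gene."""

    gene_props: pd.Series  # p_g
    depths: np.ndarray  # N_i
    dispersion: pd.Series  # a_g >= 0

    def mean(self) -> np.ndarray:
        return np.outer(self.depths, self.gene_props.to_numpy())

    def variance(self) -> np.ndarray:
        mu = self.mean()
        return mu * (1.0 + self.dispersion.to_numpy()[None, :] * mu)

    def standardized_residuals(self, counts: np.ndarray) -> np.ndarray:
        """(x - mu) / sigma; spots where the null variance vanishes get 0."""
        mu = self.mean()
        var = mu * (1.0 + self.dispersion.to_numpy()[None, :] * mu)
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (np.asarray(counts, dtype=float) - mu) / sd
        r[sd == 0] = 0.0
        return r


def _dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def fit_null_model(
    counts, depths: np.ndarray | None = None, genes: pd.Index | None = None
) -> NullModel:
    """Moment-matched NB null: ``p_g`` from pooled proportions, dispersion
    from the excess of observed over Poisson variance across spots.

    Genes with zero total count must be removed beforehand (their proportion
    and dispersion are undefined); ``depths`` defaults to the row sums of the
    supplied matrix.
    """
    X = _dense(counts)
    if X.shape[0] < 2:
        raise ValueError("need at least two spots to fit a null model")
    if depths is None:
        depths = X.sum(axis=1)
    depths = np.asarray(depths, dtype=float)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    if genes is None:
        genes = pd.RangeIndex(X.shape[1])
    genes = pd.Index(genes)

    totals = X.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("genes with zero total count must be excluded first")
    p = totals / depths.sum()
    mu = np.outer(depths, p)
    resid2 = (X - mu) ** 2
    # Var = mu + a * mu^2  =>  a = sum(resid^2 - mu) / sum(mu^2), floored at 0
    num = (resid2 - mu).sum(axis=0)
    den = (mu**2).sum(axis=0)
    a = np.maximum(0.0, num / np.maximum(den, 1e-300))
    return NullModel(
        gene_props=pd.Series(p, index=genes, name="p"),
        depths=depths,
        dispersion=pd.Series(a, index=genes, name="dispersion"),
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _exchangeability_mean(R: np.ndarray, graph: SpatialGraph) -> np.ndarray:
    """Exact permutation-null mean of H per gene.

    Averaging H over all spot permutations gives
    ``sum(w^2) * ((sum r)^2 - sum r^2) / (n (n-1))``; because the fitted null
    drives each gene's residual sum to ~0 this is ~ -sum(w^2)/(n-1), a
    finite-sample offset that would otherwise bias every z-score negative.
    """
    n = R.shape[0]
    return graph.sum_w2 * (R.sum(axis=0) ** 2 - (R**2).sum(axis=0)) / (n * (n - 1))


def local_autocorrelation(
    counts, graph: SpatialGraph, null: NullModel, genes: pd.Index | None = None
) -> pd.DataFrame:
    """Per-gene spatial autocorrelation H, z, two-sided normal p, BH FDR.

    ``H`` is the raw edge sum of residual products; ``z`` standardizes it
    against the exchangeability null (exact permutation mean, independence
    variance ``sum(w^2)``).
    """
    X = _dense(counts)
    genes = pd.Index(genes) if genes is not None else null.gene_props.index
    R = null.standardized_residuals(X)
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    H = (R[i] * R[j] * graph.weights[:, None]).sum(axis=0)
    var = graph.sum_w2
    z = (H - _exchangeability_mean(R, graph)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"H": H, "z": z, "pval": p, "fdr": fdr}, index=genes
    ).rename_axis("gene")


def pairwise_local_correlation(
    counts,
    graph: SpatialGraph,
    null: NullModel,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Symmetrized cross-gene local correlation z matrix.

    ``C_gh = sum_{(i,j) in E} w_ij (x~_gi x~_hj + x~_hi x~_gj) / 2`` with each
    unordered spot pair counted once. Under the independence null each edge
    contributes two half-weighted products with vanishing cross-covariance,
    so ``Var[C_gh] = sum w^2 / 2`` for distinct genes (validated against the
    permutation null), while the diagonal reduces to the autocorrelation
    statistic with ``Var = sum w^2``; each entry is standardized by its own
    null variance, so the diagonal equals the autocorrelation z.
    """
    all_genes = null.gene_props.index
    X = _dense(counts)
    R = null.standardized_residuals(X)
    if genes is not None:
        genes = pd.Index(genes)
        idx = all_genes.get_indexer(genes)
        if (idx < 0).any():
            raise KeyError(
                f"genes not in the analysis set: {list(genes[idx < 0][:5])}"
            )
        R = R[:, idx]
    else:
        genes = all_genes
    A = graph.adjacency()
    M = R.T @ (A @ R)  # ordered-pair sums
    C = (M + M.T) / 4.0
    z = C / np.sqrt(graph.sum_w2 / 2.0)
    # self-pairs reduce to the autocorrelation statistic: independence
    # variance sum(w^2) and the exchangeability-mean centering
    diag = (np.diagonal(C) - _exchangeability_mean(R, graph)) / np.sqrt(
        graph.sum_w2
    )
    np.fill_diagonal(z, diag)
    return pd.DataFrame(z, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


@dataclass
class ModuleSet:
    """Gene-to-module assignment (-1 = unassigned) with the evidence that
    produced it."""

    assignments: pd.Series
    pairwise_z: pd.DataFrame
    merge_tree: list[tuple] = field(default_factory=list)
    z_threshold: float = float("nan")
    min_gene_threshold: int = 15
    fdr_threshold: float = 0.05

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, m in self.assignments.items():
            if m >= 0:
                out.setdefault(int(m), []).append(g)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def _bh_z_threshold(z_upper: np.ndarray, fdr_threshold: float) -> float:
    """Smallest pairwise z whose one-sided BH-adjusted p stays below the FDR
    threshold; +inf when no pair is significant."""
    if len(z_upper) == 0:
        return float("inf")
    p = stats.norm.sf(z_upper)
    rej = multipletests(p, alpha=fdr_threshold, method="fdr_bh")[0]
    if not rej.any():
        return float("inf")
    return float(z_upper[rej].min())


def extract_modules(
    pairwise_z: pd.DataFrame,
    min_gene_threshold: int = 15,
    fdr_threshold: float = 0.05,
    core_only: bool = True,
) -> ModuleSet:
    """Bottom-up agglomeration of genes by pairwise local-correlation z.

    Clusters start as singletons; the pair of clusters with the highest
    average cross-pair z merges while that linkage stays above the z cutoff
    at which the one-sided BH-adjusted p of a pair falls below
    ``fdr_threshold``. Ties break on the lexicographically smallest
    (minimum-gene-index) pair. Clusters smaller than ``min_gene_threshold``
    are left unassigned (-1) when ``core_only``.
    """
    genes = list(pairwise_z.index)
    Z = pairwise_z.to_numpy(dtype=float)
    if Z.shape[0] != Z.shape[1] or not np.allclose(Z, Z.T, atol=1e-8):
        raise ValueError("pairwise z matrix must be symmetric")
    n = len(genes)
    if n == 0:
        return ModuleSet(
            assignments=pd.Series(dtype=int),
            pairwise_z=pairwise_z,
            min_gene_threshold=min_gene_threshold,
            fdr_threshold=fdr_threshold,
        )
    iu = np.triu_indices(n, k=1)
    z_thr = _bh_z_threshold(Z[iu], fdr_threshold) if n > 1 else float("inf")

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    # sum of cross-pair z between clusters, for O(1) average-linkage updates
    cross = Z.copy()
    np.fill_diagonal(cross, 0.0)
    sizes = {i: 1 for i in range(n)}
    merge_tree: list[tuple] = []

    def linkage(a: int, b: int) -> float:
        return cross[a, b] / (sizes[a] * sizes[b])

    active = sorted(clusters)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                li = linkage(a, b)
                # tie-break: lexicographically smallest gene-index pair
                key = (-li, min(clusters[a][0], clusters[b][0]),
                       max(clusters[a][0], clusters[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b, li)
        _, a, b, li = best
        if not (li >= z_thr):
            break
        clusters[a] = sorted(clusters[a] + clusters[b])
        sizes[a] += sizes[b]
        for c in active:
            if c not in (a, b):
                cross[a, c] += cross[b, c]
                cross[c, a] = cross[a, c]
        merge_tree.append((a, b, li, len(clusters[a])))
        del clusters[b], sizes[b]
        active.remove(b)

    assignments = np.full(n, -1, dtype=int)
    next_id = 0
    for c in sorted(clusters, key=lambda c: min(clusters[c])):
        members = clusters[c]
        if len(members) >= min_gene_threshold or (not core_only and len(members) > 1):
            assignments[members] = next_id
            next_id += 1
    return ModuleSet(
        assignments=pd.Series(assignments, index=pd.Index(genes, name="gene")),
        pairwise_z=pairwise_z,
        merge_tree=merge_tree,
        z_threshold=z_thr,
        min_gene_threshold=min_gene_threshold,
        fdr_threshold=fdr_threshold,
    )


def module_scores(
    counts, module_set: ModuleSet, graph: SpatialGraph, null: NullModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw and neighborhood-smoothed per-spot module scores.

    Raw score: mean standardized residual over the module's genes. Smoothed
    score: average of the raw score over the spot and its graph neighbors.
    """
    mods = module_set.modules
    if not mods:
        raise ValueError("module set is empty")
    X = _dense(counts)
    R = null.standardized_residuals(X)
    gene_pos = {g: i for i, g in enumerate(null.gene_props.index)}
    raw = {}
    for m, genes in sorted(mods.items()):
        cols = [gene_pos[g] for g in genes]
        raw[f"module_{m}"] = R[:, cols].mean(axis=1)
    raw_df = pd.DataFrame(raw)
    A = graph.adjacency()
    denom = np.asarray(A.sum(axis=1)).ravel() + 1.0
    smooth = (A @ raw_df.to_numpy() + raw_df.to_numpy()) / denom[:, None]
    return raw_df, pd.DataFrame(smooth, columns=raw_df.columns)


# ---------------------------------------------------------------------------
# model/results wrapper
# ---------------------------------------------------------------------------


class SpatialCoexpressionResults:
    """Fitted spatial co-expression analysis.

    Attributes
    ----------
    autocorrelation : pandas.DataFrame
        Per-gene H, z, p and BH FDR.
    significant_genes : pandas.Index
        Genes below the autocorrelation FDR threshold.
    pairwise_z : pandas.DataFrame
        Local-correlation z among significant genes.
    modules : ModuleSet
    """

    def __init__(self, model, autocorr, significant, pairwise_z, modules):
        self.model = model
        self.autocorrelation = autocorr
        self.significant_genes = significant
        self.pairwise_z = pairwise_z
        self.modules = modules

    def module_scores(self, smoothed: bool = True) -> pd.DataFrame:
        raw, smooth = module_scores(
            self.model.counts, self.modules, self.model.graph, self.model.null
        )
        out = smooth if smoothed else raw
        return out.set_index(pd.Index(self.model.spot_names, name="spot"))

    def summary(self) -> str:
        ac = self.autocorrelation
        lines = [
            "Spatial co-expression analysis (KNN graph, NB null)",
            f"  spots: {self.model.counts.shape[0]}   genes tested: {len(ac)}"
            f"   edges: {self.model.graph.n_edges} (k={self.model.graph.k})",
            f"  significant autocorrelation (FDR < "
            f"{self.model.autocorr_fdr:g}): {len(self.significant_genes)}",
            f"  modules (>= {self.modules.min_gene_threshold} genes): "
            f"{self.modules.n_modules}",
        ]
        for m, genes in sorted(self.modules.modules.items()):
            head = ", ".join(genes[:5]) + (", ..." if len(genes) > 5 else "")
            lines.append(f"    module {m}: {len(genes)} genes ({head})")
        return "\n".join(lines)


class SpatialCoexpression:
    """Model object: counts on spot coordinates -> autocorrelation + modules.

    Parameters mirror the production pipeline: ``k=6`` equal-weight neighbors
    restricted within samples, autocorrelation FDR 0.01, module FDR 0.05 and
    a 15-gene module floor.
    """

    def __init__(
        self,
        counts,
        coords: np.ndarray,
        sample_ids: np.ndarray | None = None,
        genes: pd.Index | None = None,
        spot_names: Sequence | None = None,
        k: int = 6,
        autocorr_fdr: float = 0.01,
        module_fdr: float = 0.05,
        min_gene_threshold: int = 15,
        core_only: bool = True,
        depths: np.ndarray | None = None,
    ):
        X = _dense(counts)
        genes = pd.Index(genes) if genes is not None else pd.RangeIndex(X.shape[1])
        keep = X.sum(axis=0) > 0  # zero-total genes are excluded
        self.counts = X[:, keep]
        self.genes = genes[keep]
        self.spot_names = (
            list(spot_names) if spot_names is not None else list(range(X.shape[0]))
        )
        self.graph = build_knn_graph(coords, sample_ids, k=k)
        self.null = fit_null_model(self.counts, depths=depths, genes=self.genes)
        self.autocorr_fdr = autocorr_fdr
        self.module_fdr = module_fdr
        self.min_gene_threshold = min_gene_threshold
        self.core_only = core_only

    def fit(self) -> SpatialCoexpressionResults:
        ac = local_autocorrelation(self.counts, self.graph, self.null, self.genes)
        significant = ac.index[ac["fdr"] < self.autocorr_fdr]
        if len(significant) > 0:
            pz = pairwise_local_correlation(
                self.counts, self.graph, self.null, genes=significant
            )
            mods = extract_modules(
                pz,
                min_gene_threshold=self.min_gene_threshold,
                fdr_threshold=self.module_fdr,
                core_only=self.core_only,
            )
        else:
            pz = pd.DataFrame(index=pd.Index([]), columns=pd.Index([]))
            mods = ModuleSet(
                assignments=pd.Series(dtype=int),
                pairwise_z=pz,
                min_gene_threshold=self.min_gene_threshold,
                fdr_threshold=self.module_fdr,
            )
        return SpatialCoexpressionResults(self, ac, significant, pz, mods)
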