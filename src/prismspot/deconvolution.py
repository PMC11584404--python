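"""Reference-based deconvolution of spatial spots by Gibbs sampling.

A spot's counts are modelled as a multinomial mixture of cell-type expression
profiles: for spot ``s`` with depth ``N_s``,

    x_s ~ Multinomial(N_s, sum_k theta_sk * phi_k),

with a flat Dirichlet prior ``theta_s ~ Dir(alpha)``. The conjugate Gibbs
sampler alternates (i) allocating each gene's count to cell types with
probability proportional to ``theta_sk * phi_kg`` and (ii) drawing
``theta_s ~ Dir(alpha + allocated totals)``. Posterior means of the fractions
(``theta``, the field's mu) and of the per-type allocated counts (``Z``, the
field's U/z) are retained; allocation conserves counts exactly, so
``sum_k Z[s,k,g] == x[s,g]``.

Marker selection (pairwise Welch t-tests on log-normalized expression, with
tumor types compared only against non-tumor types) and reference-profile
construction live here as well, as do the exhaustive-enumeration posterior
used for validation, tumor-count extraction and technical-replicate
concordance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.special import gammaln

from .datasets import SpatialDataset
from .simulate import ReferenceData

__all__ = [
    "MarkerSelection",
    "ReferenceProfile",
    "GibbsConfig",
    "DeconvolutionResults",
    "MixtureDeconvolution",
    "select_markers",
    "build_reference",
    "deconvolve",
    "tumor_expression",
    "replicate_concordance",
    "enumerate_posterior_theta",
]


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------


@dataclass
class MarkerSelection:
    """Per-type marker gene lists with the statistics that selected them."""

    markers: dict[str, list[str]]
    stats: pd.DataFrame  # per (type, gene): max_p, min_lfc over comparisons
    p_threshold: float
    fc_threshold: float

    @property
    def union(self) -> pd.Index:
        seen: dict[str, None] = {}
        for genes in self.markers.values():
            for g in genes:
                seen.setdefault(g, None)
        return pd.Index(list(seen), name="gene")


def _log_normalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1
    return np.log2(counts / lib * scale + 1.0)


def _welch(m1, v1, n1, m2, v2, n2):
    """Vectorized Welch t-test; returns (t, two-sided p)."""
    se2 = v1 / n1 + v2 / n2
    se2 = np.maximum(se2, 1e-300)
    t = (m1 - m2) / np.sqrt(se2)
    df_num = se2**2
    df_den = (v1 / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1)
    df = df_num / np.maximum(df_den, 1e-300)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # identical-sample degenerate case: no evidence either way
    p = np.where(se2 <= 1e-290, 1.0, p)
    return t, p


def select_markers(
    ref: ReferenceData | tuple,
    coarse_labels: Mapping[str, str] | None = None,
    tumor_coarse: str = "tumor",
    p_threshold: float = 0.01,
    fc_threshold: float = 0.1,
    allow_empty: bool = False,
) -> MarkerSelection:
    """Select per-type upregulated markers by pairwise Welch t-tests.

    A gene is a marker of fine type ``t`` when, across all required pairwise
    comparisons, its maximum p-value is below ``p_threshold`` and its minimum
    log2 fold change (difference of mean log2-normalized expression) exceeds
    ``fc_threshold``. Fine types whose coarse label equals ``tumor_coarse``
    are compared only against non-tumor fine types, retaining the maximum
    number of tumor-specific genes.
    """
    if isinstance(ref, tuple):
        counts, labels, genes = ref
        ref = ReferenceData(
            counts=sparse.csr_matrix(counts),
            genes=pd.Index(genes),
            cells=pd.RangeIndex(counts.shape[0]),
            labels=pd.Series(np.asarray(labels), index=pd.RangeIndex(counts.shape[0])),
        )
    coarse = dict(coarse_labels or ref.coarse_labels or {})
    labels = np.asarray(ref.labels)
    types = list(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("marker selection needs at least two cell types")
    X = _log_normalize(np.asarray(ref.counts.todense(), dtype=float))

    mean, var, n_cells = {}, {}, {}
    usable = []
    for t in types:
        m = labels == t
        if m.sum() < 2:
            warnings.warn(f"type {t!r} has <2 cells; excluded from marker selection")
            continue
        usable.append(t)
        mean[t] = X[m].mean(axis=0)
        var[t] = X[m].var(axis=0, ddof=1)
        n_cells[t] = int(m.sum())
    if len(usable) < 2:
        raise ValueError("fewer than two usable cell types")

    def opponents(t: str) -> list[str]:
        if coarse.get(t, t) == tumor_coarse:
            opp = [u for u in usable if coarse.get(u, u) != tumor_coarse]
            return opp or [u for u in usable if u != t]
        return [u for u in usable if u != t]

    markers: dict[str, list[str]] = {}
    rows = []
    for t in usable:
        max_p = np.zeros(X.shape[1])
        min_lfc = np.full(X.shape[1], np.inf)
        for u in opponents(t):
            _, p = _welch(mean[t], var[t], n_cells[t], mean[u], var[u], n_cells[u])
            lfc = mean[t] - mean[u]
            max_p = np.maximum(max_p, p)
            min_lfc = np.minimum(min_lfc, lfc)
        sel = (max_p < p_threshold) & (min_lfc > fc_threshold)
        markers[t] = list(ref.genes[sel])
        rows.append(
            pd.DataFrame(
                {
                    "cell_type": t,
                    "gene": ref.genes,
                    "max_p": max_p,
                    "min_lfc": min_lfc,
                    "selected": sel,
                }
            )
        )
    sel_stats = pd.concat(rows, ignore_index=True)
    result = MarkerSelection(
        markers=markers,
        stats=sel_stats,
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
    )
    if len(result.union) == 0 and not allow_empty:
        raise ValueError("no gene passed the marker thresholds for any type")
    return result


# ---------------------------------------------------------------------------
# reference profile
# ---------------------------------------------------------------------------


@dataclass
class ReferenceProfile:
    """Per-type expression fractions over a gene panel (rows sum to 1)."""

    phi: np.ndarray
    type_names: list[str]
    gene_names: pd.Index
    pseudo_min: float = 0.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.gene_names = pd.Index(self.gene_names)
        if self.phi.shape != (len(self.type_names), len(self.gene_names)):
            raise ValueError("phi shape does not match type/gene names")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1 within 1e-9")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.type_names, columns=self.gene_names)


def build_reference(
    ref: ReferenceData,
    gene_panel: Sequence[str],
    pseudo_min: float = 0.0,
    labels: pd.Series | None = None,
) -> ReferenceProfile:
    """Sum reference counts per type over the panel and normalize to fractions.

    Fractions below ``pseudo_min`` are floored at it and the row renormalized;
    ``pseudo_min=0`` keeps zeros (maximal contrast between types) but requires
    every type to have signal on the panel.
    """
    panel = pd.Index(gene_panel)
    idx = ref.genes.get_indexer(panel)
    if (idx < 0).any():
        raise ValueError("gene panel contains genes absent from the reference")
    labels = ref.labels if labels is None else labels
    lab = np.asarray(labels)
    types = list(pd.unique(lab))
    counts = np.asarray(ref.counts.todense(), dtype=float)[:, idx]
    phi = np.vstack([counts[lab == t].sum(axis=0) for t in types])
    totals = phi.sum(axis=1)
    if (totals == 0).any() and pseudo_min <= 0:
        bad = [t for t, s in zip(types, totals) if s == 0]
        raise ValueError(f"types with all-zero panel counts at pseudo_min=0: {bad}")
    totals[totals == 0] = 1.0
    phi = phi / totals[:, None]
    if pseudo_min > 0:
        phi = np.maximum(phi, pseudo_min)
        phi = phi / phi.sum(axis=1, keepdims=True)
    elif (phi.sum(axis=1) == 0).any():
        raise ValueError("unidentifiable all-zero profile at pseudo_min=0")
    return ReferenceProfile(
        phi=phi, type_names=[str(t) for t in types], gene_names=panel,
        pseudo_min=pseudo_min,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class GibbsConfig:
    """Sampler settings: flat Dirichlet prior, 1,000-step chain with a
    500-step burn-in and thinning of 2 by default."""

    alpha: float = 1.0
    chain_length: int = 1000
    burn_in: int = 500
    thinning: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


class DeconvolutionResults:
    """Posterior summaries from :class:`MixtureDeconvolution.fit`.

    Attributes
    ----------
    theta : pandas.DataFrame
        Spot-by-type posterior-mean cell-type fractions (rows sum to 1).
    Z : numpy.ndarray
        ``(n_spots, n_types, n_genes)`` posterior-mean allocated counts;
        summing over types recovers the observed counts.
    zero_spots : list
        Spots with zero total count; their fractions are the prior mean.
    """

    def __init__(self, model, theta, Z, retained_sample_count, zero_spots):
        self.model = model
        self.theta = theta
        self.Z = Z
        self.retained_sample_count = retained_sample_count
        self.zero_spots = zero_spots

    @property
    def type_names(self) -> list[str]:
        return list(self.theta.columns)

    def type_expression(self, types: Sequence[str] | str) -> pd.DataFrame:
        """Posterior-mean counts allocated to the given type(s), summed."""
        if isinstance(types, str):
            types = [types]
        idx = [self.type_names.index(t) for t in types]
        M = self.Z[:, idx, :].sum(axis=1)
        return pd.DataFrame(M, index=self.theta.index, columns=self.model.gene_names)

    def tumor_expression(self, tumor_types: Sequence[str]) -> pd.DataFrame:
        return tumor_expression(self, tumor_types)

    def summary(self) -> str:
        lines = [
            "Mixture deconvolution (conjugate Gibbs sampler)",
            f"  spots: {self.theta.shape[0]}   genes: {len(self.model.gene_names)}"
            f"   cell types: {self.theta.shape[1]}",
            f"  chain: {self.model.config.chain_length} (burn-in "
            f"{self.model.config.burn_in}, thinning {self.model.config.thinning}, "
            f"retained {self.retained_sample_count})",
            f"  alpha (Dirichlet prior): {self.model.config.alpha}",
            "",
            "  posterior mean fraction by type:",
        ]
        for t, m in self.theta.mean(axis=0).items():
            lines.append(f"    {t:<16s} {m:8.4f}")
        if self.zero_spots:
            lines.append(f"  zero-count spots set to prior mean: {len(self.zero_spots)}")
        return "\n".join(lines)


class MixtureDeconvolution:
    """Model object tying spot counts to a reference profile.

    Parameters
    ----------
    spots
        :class:`SpatialDataset` (or a dense/sparse spot-by-gene matrix with a
        matching gene index).
    reference
        :class:`ReferenceProfile` whose panel the spots are restricted to.
    config
        :class:`GibbsConfig` sampler settings.
    min_spots_per_gene
        Panel genes expressed in fewer spots are removed before sampling.
    """

    def __init__(
        self,
        spots: SpatialDataset,
        reference: ReferenceProfile,
        config: GibbsConfig | None = None,
        min_spots_per_gene: int = 4,
    ):
        self.config = config or GibbsConfig()
        self.reference = reference
        panel = reference.gene_names
        shared = panel[panel.isin(spots.genes)]
        if len(shared) == 0:
            raise ValueError("no overlap between spot genes and reference panel")
        data = spots.subset_genes(shared)
        expressed = np.asarray((data.counts > 0).sum(axis=0)).ravel()
        keep = expressed >= min_spots_per_gene
        if keep.sum() == 0:
            raise ValueError(
                f"no panel gene expressed in >= {min_spots_per_gene} spots"
            )
        self.gene_names = shared[keep]
        self.spot_names = data.spots
        self.counts = np.asarray(
            data.counts[:, np.flatnonzero(keep)].todense(), dtype=np.int64
        )
        ridx = panel.get_indexer(self.gene_names)
        phi = reference.phi[:, ridx]
        col_zero = phi.sum(axis=0) == 0
        if col_zero.any():
            raise ValueError(
                f"reference profile all-zero for genes {list(self.gene_names[col_zero][:5])}"
            )
        self.phi = phi
        self.type_names = list(reference.type_names)

    def fit(
        self,
        seed: int | None = None,
        refine_types: Sequence[str] | None = None,
    ) -> DeconvolutionResults:
        """Run the allocation/fraction Gibbs sampler.

        ``refine_types`` enables an optional second pass for robustness to
        platform differences between reference and spots: after the first
        pass, the profiles of the named types are re-estimated from their
        pooled posterior-mean allocated counts and the sampler is rerun with
        the updated profiles. Off by default.
        """
        res = self._run_chain(seed, self.phi)
        if refine_types:
            idx = [self.type_names.index(t) for t in refine_types]
            phi = self.phi.copy()
            pooled = res.Z.sum(axis=0)  # (K, G)
            for k in idx:
                total = pooled[k].sum()
                if total > 0:
                    phi[k] = pooled[k] / total
            res = self._run_chain(None if seed is None else seed + 1, phi)
        return res

    def _run_chain(self, seed: int | None, phi: np.ndarray) -> DeconvolutionResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        X = self.counts  # (S, G)
        S, G = X.shape
        K = phi.shape[0]

        zero_spots = list(self.spot_names[X.sum(axis=1) == 0])

        theta = np.full((S, K), 1.0 / K)
        theta_acc = np.zeros((S, K))
        Z_acc = np.zeros((S, K, G))
        retained = 0

        # genes with a positive count somewhere; others never allocate
        phiT = np.ascontiguousarray(phi.T)  # (G, K)
        for it in range(cfg.chain_length):
            # p[s, g, k] ~ theta[s, k] * phi[k, g]
            p = theta[:, None, :] * phiT[None, :, :]
            norm = p.sum(axis=2, keepdims=True)
            bad = norm[..., 0] <= 0
            if bad.any():
                # zero mixture mass despite a positive phi column (underflow
                # guard): fall back to uniform over types with phi > 0
                fallback = (phiT > 0).astype(float)
                fallback /= np.maximum(fallback.sum(axis=1, keepdims=True), 1)
                p[bad] = np.broadcast_to(fallback, (S, G, K))[bad]
                norm = p.sum(axis=2, keepdims=True)
            p = p / norm
            alloc = rng.multinomial(X, p)  # (S, G, K)
            n_sk = alloc.sum(axis=1)  # (S, K)
            gam = rng.standard_gamma(cfg.alpha + n_sk)
            theta = gam / gam.sum(axis=1, keepdims=True)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
                theta_acc += theta
                Z_acc += np.swapaxes(alloc, 1, 2)
                retained += 1

        theta_mean = theta_acc / retained
        Z_mean = Z_acc / retained
        if zero_spots:
            zi = self.spot_names.get_indexer(pd.Index(zero_spots))
            theta_mean[zi] = 1.0 / K
        theta_df = pd.DataFrame(
            theta_mean, index=self.spot_names, columns=self.type_names
        )
        return DeconvolutionResults(self, theta_df, Z_mean, retained, zero_spots)


def deconvolve(
    spots: SpatialDataset,
    reference: ReferenceProfile,
    config: GibbsConfig | None = None,
    min_spots_per_gene: int = 4,
    seed: int | None = None,
) -> DeconvolutionResults:
    """Functional wrapper around :class:`MixtureDeconvolution`."""
    return MixtureDeconvolution(
        spots, reference, config=config, min_spots_per_gene=min_spots_per_gene
    ).fit(seed=seed)


# ---------------------------------------------------------------------------
# exhaustive-enumeration posterior (validation oracle)
# ---------------------------------------------------------------------------


def enumerate_posterior_theta(
    counts: Sequence[int], phi: np.ndarray, alpha: float = 1.0
) -> np.ndarray:
    """Exact posterior mean of theta for one spot by brute-force enumeration.

    Sums over every possible allocation of each gene's count to the cell
    types; tractable only for tiny instances (total count <= ~10, <= 3
    types). Serves as an independent check on the Gibbs sampler — it shares
    no code with it.
    """
    counts = np.asarray(counts, dtype=int)
    phi = np.asarray(phi, dtype=float)
    K, G = phi.shape
    if counts.shape != (G,):
        raise ValueError("counts must have one entry per gene")

    def compositions(n: int, k: int):
        if k == 1:
            yield (n,)
            return
        for first in range(n + 1):
            for rest in compositions(n - first, k - 1):
                yield (first, *rest)

    per_gene = []
    for g in range(G):
        opts = []
        safe_log = np.log(np.where(phi[:, g] > 0, phi[:, g], 1.0))
        for comp in compositions(int(counts[g]), K):
            comp = np.asarray(comp)
            if np.any((comp > 0) & (phi[:, g] == 0)):
                continue  # impossible allocation
            logw = (
                gammaln(counts[g] + 1)
                - gammaln(comp + 1).sum()
                + (comp * safe_log).sum()
            )
            opts.append((comp, logw))
        per_gene.append(opts)

    N = int(counts.sum())
    log_total = -np.inf
    mean_acc = np.zeros(K)
    terms = []
    for combo in itertools.product(*per_gene):
        n_k = np.sum([c for c, _ in combo], axis=0) if combo else np.zeros(K, int)
        logw = sum(lw for _, lw in combo) + gammaln(alpha + n_k).sum()
        terms.append((n_k, logw))
    logws = np.array([lw for _, lw in terms])
    logws -= logws.max()
    ws = np.exp(logws)
    ws /= ws.sum()
    for (n_k, _), w in zip(terms, ws):
        mean_acc += w * (alpha + n_k) / (K * alpha + N)
    return mean_acc


# ---------------------------------------------------------------------------
# tumor counts and replicate concordance
# ---------------------------------------------------------------------------


def tumor_expression(
    result: DeconvolutionResults, tumor_types: Sequence[str]
) -> pd.DataFrame:
    """Ceiling of posterior-mean counts summed across the tumor types.

    Rounding up after summation yields nonnegative integers suitable for
    count-based null models; because allocation conserves counts, entries
    never exceed the observed counts' ceiling.
    """
    if len(tumor_types) == 0:
        raise ValueError("tumor_types must be non-empty")
    unknown = [t for t in tumor_types if t not in result.type_names]
    if unknown:
        raise KeyError(f"unknown cell types: {unknown}")
    M = result.type_expression(list(tumor_types)).to_numpy()
    out = np.ceil(M - 1e-9).astype(np.int64)
    out = np.maximum(out, 0)
    return pd.DataFrame(
        out, index=result.theta.index, columns=result.model.gene_names
    )


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")  # undefined under zero variance, reported as NaN
    return float(np.corrcoef(a, b)[0, 1])


def replicate_concordance(
    theta_a: pd.DataFrame,
    theta_b: pd.DataFrame,
    regions_a: np.ndarray,
    regions_b: np.ndarray,
) -> dict[str, pd.Series]:
    """Region-averaged fraction concordance between technical replicates.

    Returns per-type Pearson r across regions and per-region Pearson r across
    types; zero-variance vectors yield NaN ("undefined") rather than an error.
    """
    if list(theta_a.columns) != list(theta_b.columns):
        raise ValueError("replicates must share cell types")
    ra = pd.Series(np.asarray(regions_a), index=theta_a.index)
    rb = pd.Series(np.asarray(regions_b), index=theta_b.index)
    mean_a = theta_a.groupby(ra).mean()
    mean_b = theta_b.groupby(rb).mean()
    common = mean_a.index.intersection(mean_b.index)
    dropped = set(mean_a.index).symmetric_difference(mean_b.index)
    if dropped:
        warnings.warn(f"regions missing from one replicate dropped: {sorted(dropped)}")
    mean_a, mean_b = mean_a.loc[common], mean_b.loc[common]
    per_type = pd.Series(
        {
            t: _pearson_or_nan(mean_a[t].to_numpy(), mean_b[t].to_numpy())
            for t in theta_a.columns
        },
        name="pearson_r",
    )
    per_region = pd.Series(
        {
            r: _pearson_or_nan(
                mean_a.loc[r].to_numpy(), mean_b.loc[r].to_numpy()
            )
            for r in common
        },
        name="pearson_r",
    )
    return {"per_type": per_type, "per_region": per_region, "region_means_a": mean_a,
            "region_means_b": mean_b}
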