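"""Synthetic single-cell references and spatial spot datasets with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a handful of cell types with strong marker genes, Visium-like spots
whose counts are multinomial mixtures of type profiles, smoothly varying
cell-type fraction fields over a lattice (Gaussian bumps pushed through a
softmax), planted spatially coherent tumor gene modules acting only through
the tumor-type profiles, a non-tumor "confounder" type whose spatial bump
colocalizes with one planted module, heavy-tailed library sizes, technical
replicates, and binomial read-thinning.

Everything is driven by one root seed; each operation draws from a fixed
child stream so components are reproducible independently of call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .datasets import GroundTruth, SpatialDataset

# fixed child-stream tags: one root seed, per-operation independent streams
_STREAMS = {"rates": 7, "reference": 11, "spatial": 23, "thin": 37, "replicate": 41}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-operation generator derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _STREAMS[stream]])
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic tissue.

    Defaults describe a 210-spot lattice mixing two tumor types with four
    non-tumor types at ~2,000 UMIs per spot, two planted 20-gene tumor
    modules, and one non-tumor type colocalized with the first module.
    """

    n_types: int = 6
    n_genes: int = 400
    markers_per_type: int = 10
    marker_fold: float = 20.0
    grid_shape: tuple[int, int] = (15, 14)
    n_modules: int = 2
    module_size: int = 20
    module_bump_centers: Sequence[tuple[float, float]] | None = None
    module_amplitude: float = 2.5
    module_tumor_fold: float = 15.0
    tumor_types: tuple[int, ...] = (0, 1)
    depth_mean: float = 2000.0
    depth_dispersion: float = 0.35
    cells_per_type: int = 200
    ref_depth_mean: float = 3000.0
    ref_dispersion: float = 0.15
    fraction_jitter: float = 0.6
    tumor_only: bool = False
    n_noise_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if not self.tumor_types:
            raise ValueError("tumor_types must be non-empty")
        if max(self.tumor_types) >= self.n_types:
            raise ValueError("tumor_types outside type range")
        if self.module_size < 1:
            raise ValueError("module_size must be >= 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                "infeasible marker allocation: markers_per_type * n_types "
                f"= {self.markers_per_type * self.n_types} > n_genes = {self.n_genes}"
            )
        needed = self.markers_per_type * self.n_types + self.n_modules * self.module_size
        if needed > self.n_genes:
            raise ValueError(
                f"marker + module genes ({needed}) exceed n_genes ({self.n_genes})"
            )
        if not (0 < self.module_amplitude or self.module_amplitude == 0):
            raise ValueError("module_amplitude must be >= 0")
        if self.grid_shape[0] * self.grid_shape[1] < 1:
            raise ValueError("empty lattice")

    # ---- gene panel layout -------------------------------------------------
    @property
    def nontumor_types(self) -> tuple[int, ...]:
        return tuple(k for k in range(self.n_types) if k not in self.tumor_types)

    @property
    def confounder_type(self) -> int | None:
        """Non-tumor type whose fraction bump colocalizes with module 0."""
        nt = self.nontumor_types
        return nt[0] if nt else None

    def type_names(self) -> list[str]:
        names = []
        t_i = n_i = 0
        for k in range(self.n_types):
            if k in self.tumor_types:
                names.append(f"tumor{t_i}")
                t_i += 1
            else:
                names.append(f"stroma{n_i}")
                n_i += 1
        return names

    def gene_names(self) -> pd.Index:
        names: list[str] = []
        for k in range(self.n_types):
            names += [f"t{k}_mk{j}" for j in range(self.markers_per_type)]
        for m in range(self.n_modules):
            names += [f"mod{m}_g{j}" for j in range(self.module_size)]
        n_bg = self.n_genes - len(names)
        names += [f"bg{j}" for j in range(n_bg)]
        return pd.Index(names, name="gene")

    def marker_type(self) -> pd.Series:
        """Ground-truth marker assignment per gene (-1 = not a marker)."""
        mt = np.full(self.n_genes, -1, dtype=int)
        for k in range(self.n_types):
            lo = k * self.markers_per_type
            mt[lo : lo + self.markers_per_type] = k
        return pd.Series(mt, index=self.gene_names())

    def module_membership(self) -> pd.Series:
        mm = np.full(self.n_genes, -1, dtype=int)
        lo = self.n_types * self.markers_per_type
        for m in range(self.n_modules):
            mm[lo + m * self.module_size : lo + (m + 1) * self.module_size] = m
        return pd.Series(mm, index=self.gene_names())

    def noise_genes(self) -> list[str]:
        """Background genes reserved as spatially unstructured 'noise' panel."""
        bg = [g for g in self.gene_names() if g.startswith("bg")]
        return bg[: self.n_noise_genes]

    # ---- spatial geometry ---------------------------------------------------
    def _rel(self, rc: tuple[float, float]) -> tuple[float, float]:
        r, c = self.grid_shape
        return (rc[0] * (r - 1), rc[1] * (c - 1))

    def module_centers(self) -> list[tuple[float, float]]:
        if self.module_bump_centers is not None:
            return [tuple(map(float, c)) for c in self.module_bump_centers]
        anchors = [(0.2, 0.2), (0.75, 0.7), (0.2, 0.8), (0.8, 0.2), (0.5, 0.5)]
        return [self._rel(anchors[m % len(anchors)]) for m in range(self.n_modules)]

    def type_bumps(self) -> list[dict]:
        """Per-type logit field parameters (base, amplitude, center, width).

        Tumor-fraction bumps are broad and deliberately offset from the
        module-intensity bumps (tumor programs vary *within* tumor regions,
        they do not track tumor abundance). Non-tumor infiltration
        colocalizes with the tumor niches: the designated confounder type
        sits on module 0's bump and, when a second module and enough
        non-tumor types exist, the last non-tumor type sits on module 1's.
        """
        r, c = self.grid_shape
        sigma_t = 0.35 * max(r, c)
        sigma_n = 0.22 * max(r, c)
        tumor_anchors = [(0.35, 0.6), (0.72, 0.3), (0.5, 0.2), (0.2, 0.6), (0.8, 0.4)]
        stroma_anchors = [(0.15, 0.8), (0.85, 0.2), (0.5, 0.5), (0.1, 0.1), (0.9, 0.9)]
        bumps = []
        t_i = n_i = 0
        mod_centers = self.module_centers()
        nontumor = self.nontumor_types
        for k in range(self.n_types):
            if k in self.tumor_types:
                bumps.append(
                    dict(
                        base=0.8,
                        amp=2.0,
                        center=self._rel(tumor_anchors[t_i % len(tumor_anchors)]),
                        sigma=sigma_t,
                    )
                )
                t_i += 1
            else:
                if k == self.confounder_type and mod_centers:
                    center = mod_centers[0]  # colocalized with module 0
                elif (
                    len(nontumor) > 1
                    and k == nontumor[-1]
                    and len(mod_centers) > 1
                ):
                    center = mod_centers[1]  # infiltration over module 1
                else:
                    center = self._rel(stroma_anchors[n_i % len(stroma_anchors)])
                bumps.append(dict(base=0.0, amp=1.8, center=center, sigma=sigma_n))
                n_i += 1
        return bumps


@dataclass
class ReferenceData:
    """Simulated single-cell/nucleus reference with fine and coarse labels."""

    counts: sparse.csr_matrix
    genes: pd.Index
    cells: pd.Index
    labels: pd.Series  # fine type name per cell
    coarse_labels: dict[str, str] = field(default_factory=dict)  # fine -> coarse


# ---------------------------------------------------------------------------
# generative means
# ---------------------------------------------------------------------------


def base_rates(config: SimConfig) -> np.ndarray:
    """Per-gene baseline expression rates (log-normal across genes)."""
    rng = child_rng(config.seed, "rates")
    return rng.lognormal(mean=0.0, sigma=0.4, size=config.n_genes)


def expression_means(config: SimConfig) -> np.ndarray:
    """Type-by-gene mean expression (unnormalized rates)."""
    u = base_rates(config)
    E = np.tile(u, (config.n_types, 1))
    mt = config.marker_type().to_numpy()
    for k in range(config.n_types):
        E[k, mt == k] *= config.marker_fold
    mm = config.module_membership().to_numpy()
    for k in config.tumor_types:
        E[k, mm >= 0] *= config.module_tumor_fold
    return E


def true_profiles(config: SimConfig) -> np.ndarray:
    """Generative per-type expression fractions (rows sum to 1)."""
    E = expression_means(config)
    return E / E.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def make_reference(config: SimConfig) -> ReferenceData:
    """Draw a labelled single-cell reference with negative-binomial counts.

    Each cell of type ``k`` has expected expression proportional to the type
    mean; counts are gamma-Poisson with dispersion ``ref_dispersion`` so that
    ``Var = mu * (1 + ref_dispersion * mu)``.
    """
    rng = child_rng(config.seed, "reference")
    E = expression_means(config)
    P = E / E.sum(axis=1, keepdims=True)
    names = config.type_names()
    n_cells = config.cells_per_type * config.n_types

    depths = rng.lognormal(
        mean=np.log(config.ref_depth_mean) - 0.3**2 / 2, sigma=0.3, size=n_cells
    )
    labels = np.repeat(np.arange(config.n_types), config.cells_per_type)
    mu = depths[:, None] * P[labels]
    if config.ref_dispersion > 0:
        shape = 1.0 / config.ref_dispersion
        lam = rng.gamma(shape, mu * config.ref_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    cells = pd.Index([f"cell{i}" for i in range(n_cells)], name="cell")
    label_s = pd.Series([names[k] for k in labels], index=cells, name="cell_type")
    coarse = {
        names[k]: ("tumor" if k in config.tumor_types else names[k])
        for k in range(config.n_types)
    }
    return ReferenceData(
        counts=sparse.csr_matrix(counts),
        genes=config.gene_names(),
        cells=cells,
        labels=label_s,
        coarse_labels=coarse,
    )


# ---------------------------------------------------------------------------
# spatial dataset
# ---------------------------------------------------------------------------


def _lattice_coords(grid_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _bump(coords: np.ndarray, center: Sequence[float], sigma: float) -> np.ndarray:
    d2 = ((coords - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def fraction_field(
    config: SimConfig,
    coords: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Softmax of per-type Gaussian-bump logit fields -> simplex rows.

    When ``rng`` is given, independent per-spot logit jitter of scale
    ``fraction_jitter`` is added on top of the smooth bumps: which cell mix a
    ~55-um spot happens to capture fluctuates section-to-section, so the
    jitter is measurement-level (re-drawn for technical replicates), not part
    of the translated tissue fields.
    """
    logits = np.empty((len(coords), config.n_types))
    for k, b in enumerate(config.type_bumps()):
        logits[:, k] = b["base"] + b["amp"] * _bump(coords, b["center"], b["sigma"])
    if rng is not None and config.fraction_jitter > 0:
        logits = logits + rng.normal(
            0.0, config.fraction_jitter, size=logits.shape
        )
    if config.tumor_only:
        mask = np.full(config.n_types, -np.inf)
        mask[list(config.tumor_types)] = 0.0
        logits = logits + mask
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def module_fields(config: SimConfig, coords: np.ndarray) -> np.ndarray:
    """Planted per-module spatial intensity in [0, 1]; shape (spots, modules)."""
    sigma = 0.17 * max(config.grid_shape)
    centers = config.module_centers()
    if not centers:
        return np.zeros((len(coords), 0))
    return np.column_stack([_bump(coords, c, sigma) for c in centers])


def _spot_mixture(
    config: SimConfig,
    profiles: np.ndarray,
    fractions: np.ndarray,
    fields: np.ndarray,
) -> np.ndarray:
    """Per-spot gene proportions: planted modules act only through tumor rows."""
    S = fractions.shape[0]
    mm = config.module_membership().to_numpy()
    mix = np.zeros((S, config.n_genes))
    tumor = set(config.tumor_types)
    for k in range(config.n_types):
        phi = np.tile(profiles[k], (S, 1))
        if k in tumor and config.module_amplitude > 0 and fields.shape[1]:
            for m in range(config.n_modules):
                sel = mm == m
                phi[:, sel] *= (1.0 + config.module_amplitude * fields[:, [m]])
            phi /= phi.sum(axis=1, keepdims=True)
        mix += fractions[:, [k]] * phi
    return mix


def make_spatial_dataset(
    config: SimConfig,
    reference_profiles: np.ndarray | None = None,
    fraction_override: np.ndarray | None = None,
    sample_id: str = "S1",
    _rng: np.random.Generator | None = None,
    _coord_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[SpatialDataset, GroundTruth]:
    """Draw a lattice of spots as multinomial mixtures of type profiles.

    ``reference_profiles`` (type-by-gene, rows summing to 1) defaults to the
    generative profiles. ``fraction_override`` fixes the fraction field (for
    degenerate cases such as a pure-tumor tissue); rows must lie on the
    simplex.
    """
    profiles = (
        np.asarray(reference_profiles, dtype=float)
        if reference_profiles is not None
        else true_profiles(config)
    )
    if profiles.shape != (config.n_types, config.n_genes):
        raise ValueError(
            f"profiles shape {profiles.shape} does not match "
            f"(n_types, n_genes) = {(config.n_types, config.n_genes)}"
        )
    if not np.allclose(profiles.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("profile rows must sum to 1")

    rng = _rng if _rng is not None else child_rng(config.seed, "spatial")
    coords = _lattice_coords(config.grid_shape)
    field_coords = coords + np.asarray(_coord_offset, dtype=float)

    if fraction_override is not None:
        fractions = np.asarray(fraction_override, dtype=float)
        if fractions.shape != (len(coords), config.n_types):
            raise ValueError("fraction_override shape mismatch")
    else:
        fractions = fraction_field(config, field_coords, rng=rng)
    fields = module_fields(config, field_coords)

    mix = _spot_mixture(config, profiles, fractions, fields)

    sig = config.depth_dispersion
    depths = rng.lognormal(
        mean=np.log(config.depth_mean) - sig**2 / 2, sigma=sig, size=len(coords)
    )
    depths = np.maximum(1, np.round(depths)).astype(np.int64)
    counts = rng.multinomial(depths, mix)

    spots = pd.Index(
        [f"{sample_id}_r{int(r)}c{int(c)}" for r, c in coords], name="spot"
    )
    ds = SpatialDataset(
        counts=sparse.csr_matrix(counts),
        genes=config.gene_names(),
        spots=spots,
        coords=coords,
        sample_ids=np.repeat(sample_id, len(coords)),
        meta={"sim_config": config, "sim_profiles": profiles},
    )
    names = config.type_names()
    gt = GroundTruth(
        fractions=fractions,
        module_membership=config.module_membership(),
        spatial_field=fields,
        type_names=names,
        marker_type=config.marker_type(),
        confounder_genes=[
            g
            for g, t in config.marker_type().items()
            if t == config.confounder_type
        ],
    )
    return ds, gt


# ---------------------------------------------------------------------------
# thinning and replicates
# ---------------------------------------------------------------------------


def binomial_thin(
    dataset: SpatialDataset, rate: float, seed: int = 0
) -> SpatialDataset:
    """Downsample counts: each entry -> Binomial(count, rate); coords unchanged."""
    if not (0 < rate <= 1):
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    counts = dataset.counts.tocsr().copy()
    if rate < 1:
        rng = child_rng(seed, "thin")
        counts.data = rng.binomial(counts.data, rate)
        counts.eliminate_zeros()
    meta = dict(dataset.meta)
    meta["thin_rate"] = rate * meta.get("thin_rate", 1.0)
    return SpatialDataset(
        counts=counts,
        genes=dataset.genes,
        spots=dataset.spots,
        coords=dataset.coords,
        sample_ids=dataset.sample_ids,
        meta=meta,
    )


def make_technical_replicate(
    dataset: SpatialDataset,
    shift: tuple[float, float] = (0.0, 0.0),
    seed: int = 1,
    sample_id: str | None = None,
) -> tuple[SpatialDataset, GroundTruth]:
    """Adjacent-section replicate: same ground-truth fields translated by
    ``shift`` on the x-y plane, independent counting noise.

    Requires a dataset produced by :func:`make_spatial_dataset` (the
    generative recipe travels in ``dataset.meta``).
    """
    config: SimConfig | None = dataset.meta.get("sim_config")
    if config is None:
        raise ValueError("dataset does not carry a simulation recipe")
    rows, cols = config.grid_shape
    if abs(shift[0]) >= rows or abs(shift[1]) >= cols:
        raise ValueError(f"shift {shift} exceeds lattice extent {config.grid_shape}")

    lo = np.asarray(shift, dtype=float)
    hi = lo + np.asarray([rows - 1, cols - 1])
    clipped = []
    for k in config.tumor_types:
        c = np.asarray(config.type_bumps()[k]["center"])
        if not ((lo <= c).all() and (c <= hi).all()):
            clipped.append(k)
    if clipped and len(clipped) == len(config.tumor_types):
        warnings.warn(
            f"shift {shift} moves every tumor region off the section",
            stacklevel=2,
        )

    if sample_id is None:
        sample_id = str(dataset.sample_ids[0]) + "_rep"
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _STREAMS["replicate"]])
    )
    return make_spatial_dataset(
        config,
        reference_profiles=dataset.meta.get("sim_profiles"),
        sample_id=sample_id,
        _rng=rng,
        _coord_offset=tuple(shift),
    )


def combine_samples(
    datasets: Sequence[SpatialDataset], col_gap: float = 5.0
) -> SpatialDataset:
    """Concatenate samples into one dataset, offsetting columns so that spots
    from different samples can never overlap (neighborhoods stay within
    sample by construction and by the graph's sample restriction)."""
    if not datasets:
        raise ValueError("no datasets to combine")
    genes = datasets[0].genes
    for ds in datasets[1:]:
        if not ds.genes.equals(genes):
            raise ValueError("datasets disagree on the gene panel")
    counts = sparse.vstack([ds.counts for ds in datasets]).tocsr()
    offset = 0.0
    coords = []
    for ds in datasets:
        c = ds.coords.copy()
        c[:, 1] += offset
        coords.append(c)
        offset += ds.coords[:, 1].max() + col_gap
    return SpatialDataset(
        counts=counts,
        genes=genes,
        spots=pd.Index(np.concatenate([ds.spots for ds in datasets]), name="spot"),
        coords=np.vstack(coords),
        sample_ids=np.concatenate([ds.sample_ids for ds in datasets]),
        meta={"combined": True},
    )


def lattice_regions(
    coords: np.ndarray,
    grid_shape: tuple[int, int],
    n_row_bins: int = 2,
    n_col_bins: int = 2,
    offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Coarse rectangular region labels over the lattice (for replicate
    concordance); ``offset`` realigns a shifted replicate to the tissue frame."""
    rows, cols = grid_shape
    rc = coords + np.asarray(offset, dtype=float)
    rbin = np.clip((rc[:, 0] / rows * n_row_bins).astype(int), 0, n_row_bins - 1)
    cbin = np.clip((rc[:, 1] / cols * n_col_bins).astype(int), 0, n_col_bins - 1)
    return np.array([f"region_{r}{c}" for r, c in zip(rbin, cbin)])
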