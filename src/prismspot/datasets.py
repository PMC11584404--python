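"""In-memory containers for spot-level spatial expression data.

The package works on plain numpy/scipy/pandas objects; :class:`SpatialDataset`
bundles a sparse spot-by-gene count matrix with spot coordinates and sample
identifiers, mirroring what a 10x-style Matrix Market directory plus a
positions table contain. Conversion to :class:`anndata.AnnData` is provided
for interoperability with the scanpy ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class SpatialDataset:
    """Spot-by-gene counts with coordinates and sample identifiers.

    Parameters
    ----------
    counts
        Sparse (or dense) integer matrix, spots in rows, genes in columns.
    genes
        Gene identifiers, length equal to ``counts.shape[1]``.
    spots
        Spot barcodes, length equal to ``counts.shape[0]``.
    coords
        ``(n_spots, 2)`` array of (row, col) lattice coordinates in array
        units.
    sample_ids
        Per-spot sample label; neighborhoods never cross samples.
    """

    counts: sparse.csr_matrix
    genes: pd.Index
    spots: pd.Index
    coords: np.ndarray
    sample_ids: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not sparse.issparse(self.counts):
            self.counts = sparse.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.genes = pd.Index(self.genes)
        self.spots = pd.Index(self.spots)
        self.coords = np.asarray(self.coords, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        n, g = self.counts.shape
        if len(self.genes) != g:
            raise ValueError(
                f"gene index length {len(self.genes)} != matrix columns {g}"
            )
        if len(self.spots) != n or len(self.coords) != n or len(self.sample_ids) != n:
            raise ValueError("spot-wise arrays disagree on the number of spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMI count per spot."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with nonzero count per spot."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_genes(self, genes: pd.Index | list[str]) -> "SpatialDataset":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = pd.Index(genes)[idx < 0]
            raise KeyError(f"genes not present: {list(missing[:5])} ...")
        return SpatialDataset(
            counts=self.counts[:, idx],
            genes=pd.Index(genes),
            spots=self.spots,
            coords=self.coords,
            sample_ids=self.sample_ids,
            meta=dict(self.meta),
        )

    def subset_spots(self, mask: np.ndarray) -> "SpatialDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpatialDataset(
            counts=self.counts[idx],
            genes=self.genes,
            spots=self.spots[idx],
            coords=self.coords[idx],
            sample_ids=self.sample_ids[idx],
            meta=dict(self.meta),
        )

    def to_anndata(self):
        """Return an :class:`anndata.AnnData` view of the dataset."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(
                {"sample_id": self.sample_ids}, index=self.spots.astype(str)
            ),
            var=pd.DataFrame(index=self.genes.astype(str)),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata


@dataclass
class GroundTruth:
    """Generative ground truth attached to a simulated dataset.

    fractions
        ``(n_spots, n_types)`` simplex rows: true cell-type proportions.
    module_membership
        Per-gene planted module id (``-1`` for genes outside any module).
    spatial_field
        ``(n_spots, n_modules)`` planted module intensity in ``[0, 1]``.
    """

    fractions: np.ndarray
    module_membership: pd.Series
    spatial_field: np.ndarray
    type_names: list[str] = field(default_factory=list)
    marker_type: pd.Series | None = None
    confounder_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows = self.fractions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1 within 1e-9")
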