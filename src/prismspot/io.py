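"""Readers and writers for the pipeline's on-disk formats.

Counts travel as 10x-style Matrix Market directories (``matrix.mtx`` with
1-based indices on disk, genes-by-spots orientation, plus ``features.tsv``
and ``barcodes.tsv``); coordinates as a tab-delimited table with columns
(barcode, sample_id, row, col, x, y) in the Visium-positions dialect; all
derived results as CSV/JSON. Indices are 0-based in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .datasets import SpatialDataset

__all__ = [
    "read_counts",
    "write_counts",
    "read_coordinates",
    "write_coordinates",
    "read_spatial_dataset",
    "write_spatial_dataset",
    "read_reference",
    "write_reference",
]


def read_counts(path: str | Path) -> tuple[sparse.csr_matrix, pd.Index, pd.Index]:
    """Read counts as (spots-by-genes csr, gene index, barcode index).

    ``path`` is either a Matrix Market directory (``matrix.mtx`` stored
    genes-by-spots, as 10x writes it) or a delimited dense matrix with gene
    rows and spot columns.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        feat = path / "features.tsv"
        if not feat.exists():
            feat = path / "genes.tsv"
        barc = path / "barcodes.tsv"
        for f in (mtx, feat, barc):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
        M = sio.mmread(mtx).tocsr()
        genes = pd.read_csv(feat, sep="\t", header=None).iloc[:, 0]
        barcodes = pd.read_csv(barc, sep="\t", header=None).iloc[:, 0]
        if len(genes) == 0:
            raise ValueError(f"empty gene file {feat}")
        if len(barcodes) == 0:
            raise ValueError(f"empty barcode file {barc}")
        if M.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix.mtx is {M.shape} but features.tsv has {len(genes)} "
                f"rows and barcodes.tsv has {len(barcodes)} rows"
            )
        counts = M.T.tocsr().astype(np.int64)
        return counts, pd.Index(genes, name="gene"), pd.Index(barcodes, name="spot")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    counts = sparse.csr_matrix(df.to_numpy().T.astype(np.int64))
    return counts, pd.Index(df.index, name="gene"), pd.Index(df.columns, name="spot")


def write_counts(
    path: str | Path,
    counts: sparse.spmatrix | np.ndarray,
    genes: pd.Index,
    barcodes: pd.Index,
) -> None:
    """Write a spots-by-genes matrix as a 10x-style MTX directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    M = sparse.coo_matrix(sparse.csr_matrix(counts).T)  # genes x spots on disk
    sio.mmwrite(path / "matrix.mtx", M, field="integer")
    pd.Series(list(genes)).to_csv(path / "features.tsv", sep="\t",
                                  header=False, index=False)
    pd.Series(list(barcodes)).to_csv(path / "barcodes.tsv", sep="\t",
                                     header=False, index=False)


_COORD_COLS = ["barcode", "sample_id", "row", "col", "x", "y"]


def write_coordinates(path: str | Path, dataset: SpatialDataset) -> None:
    df = pd.DataFrame(
        {
            "barcode": list(dataset.spots),
            "sample_id": dataset.sample_ids,
            "row": dataset.coords[:, 0],
            "col": dataset.coords[:, 1],
            "x": dataset.coords[:, 1],  # micrometer-style alias of array cols
            "y": dataset.coords[:, 0],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COORD_COLS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"coordinate table missing columns {missing}")
    return df


def write_spatial_dataset(path: str | Path, dataset: SpatialDataset) -> None:
    """MTX directory + coordinates.tsv for one dataset."""
    path = Path(path)
    write_counts(path, dataset.counts, dataset.genes, dataset.spots)
    write_coordinates(path / "coordinates.tsv", dataset)


def write_reference(path: str | Path, reference) -> None:
    """MTX directory + labels.tsv (cell, cell_type, coarse_type)."""
    path = Path(path)
    write_counts(path, reference.counts, reference.genes, reference.cells)
    coarse = reference.coarse_labels or {}
    pd.DataFrame(
        {
            "cell": list(reference.cells),
            "cell_type": list(reference.labels),
            "coarse_type": [coarse.get(t, t) for t in reference.labels],
        }
    ).to_csv(path / "labels.tsv", sep="\t", index=False)


def read_reference(path: str | Path, labels_path: str | Path | None = None):
    from .simulate import ReferenceData

    path = Path(path)
    counts, genes, cells = read_counts(path)
    labels_path = Path(labels_path) if labels_path else path / "labels.tsv"
    lab = pd.read_csv(labels_path, sep="\t").set_index("cell")
    lab = lab.loc[list(cells)]
    coarse = {}
    if "coarse_type" in lab.columns:
        coarse = dict(zip(lab["cell_type"], lab["coarse_type"]))
    return ReferenceData(
        counts=counts,
        genes=genes,
        cells=cells,
        labels=pd.Series(lab["cell_type"].to_numpy(), index=cells, name="cell_type"),
        coarse_labels=coarse,
    )


def read_spatial_dataset(path: str | Path) -> SpatialDataset:
    path = Path(path)
    counts, genes, barcodes = read_counts(path)
    coords_df = read_coordinates(path / "coordinates.tsv")
    coords_df = coords_df.set_index("barcode").loc[list(barcodes)]
    return SpatialDataset(
        counts=counts,
        genes=genes,
        spots=barcodes,
        coords=coords_df[["row", "col"]].to_numpy(float),
        sample_ids=coords_df["sample_id"].to_numpy(),
    )
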