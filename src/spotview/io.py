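"""Reading and writing SRT slices and pipeline results.

A slice is a spot-by-gene count matrix plus a two-column spatial coordinate
table.  Counts may arrive as MatrixMarket (``.mtx``), delimited text, or an
AnnData ``.h5ad`` container; coordinates as delimited text with one ``x, y``
row per spot (or inside ``adata.obsm['spatial']`` for h5ad).  All outputs are
plain TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclasses.dataclass
class RawSlice:
    """One tissue slice: counts (spots x genes), coordinates, identifier."""

    counts: np.ndarray
    coords: np.ndarray
    slice_id: str
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.coords.shape != (self.counts.shape[0], 2):
            raise ValueError(
                f"slice '{self.slice_id}': counts has {self.counts.shape[0]} spots "
                f"but coords has shape {self.coords.shape}; expected "
                f"({self.counts.shape[0]}, 2)"
            )
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError(
                f"slice '{self.slice_id}': {self.counts.shape[1]} genes but "
                f"{len(self.gene_names)} gene names"
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def _default_gene_names(n: int) -> list[str]:
    return [f"g{j}" for j in range(n)]


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Load a spots-x-genes count matrix; return (dense array, gene names or None)."""
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        mat = scipy.io.mmread(path)
        return np.asarray(mat.todense() if sp.issparse(mat) else mat), None
    if suffix in (".h5ad", ".h5"):
        import anndata

        adata = anndata.read_h5ad(path)
        X = adata.X
        dense = np.asarray(X.todense() if sp.issparse(X) else X)
        return dense, list(map(str, adata.var_names))
    # delimited text; sniff the delimiter from the first line
    with open(path) as fh:
        first = fh.readline()
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    arr = np.loadtxt(path, delimiter=delim, ndmin=2)
    return arr, None


def read_coords(path: str | Path) -> np.ndarray:
    """Read an (x, y) coordinate table, one row per spot."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    coords = np.loadtxt(path, delimiter=delim, ndmin=2)
    if coords.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 coordinate columns, got {coords.shape[1]}")
    return coords


def read_slice(matrix_path: str | Path, coords_path: str | Path | None,
               slice_id: str) -> RawSlice:
    """Read one slice from a matrix file and a coordinate file.

    For ``.h5ad`` input with ``obsm['spatial']`` present, ``coords_path``
    may be ``None``.
    """
    matrix_path = Path(matrix_path)
    counts, gene_names = _read_matrix(matrix_path)
    if coords_path is None:
        if matrix_path.suffix.lower() not in (".h5ad", ".h5"):
            raise ValueError("coords_path is required for non-h5ad input")
        import anndata

        adata = anndata.read_h5ad(matrix_path)
        if "spatial" not in adata.obsm:
            raise ValueError(f"{matrix_path}: no obsm['spatial'] and no coords file")
        coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
    else:
        coords = read_coords(coords_path)
    if coords.shape[0] != counts.shape[0]:
        raise ValueError(
            f"slice '{slice_id}': counts file {matrix_path} has {counts.shape[0]} "
            f"spots but coords file has {coords.shape[0]} rows"
        )
    if gene_names is None:
        gene_names = _default_gene_names(counts.shape[1])
    return RawSlice(counts=counts, coords=coords, slice_id=slice_id,
                    gene_names=gene_names)


def write_slice_mtx(slice_: RawSlice, out_dir: str | Path) -> dict[str, Path]:
    """Write one slice as MatrixMarket counts + TSV coordinates.

    The matrix is written spots-x-genes.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / f"{slice_.slice_id}.counts.mtx",
        "coords": out_dir / f"{slice_.slice_id}.coords.tsv",
        "genes": out_dir / f"{slice_.slice_id}.genes.tsv",
    }
    scipy.io.mmwrite(paths["counts"], sp.coo_matrix(slice_.counts))
    np.savetxt(paths["coords"], slice_.coords, delimiter="\t", fmt="%.10g")
    paths["genes"].write_text("\n".join(slice_.gene_names) + "\n")
    return paths


def write_results(embeddings: np.ndarray, labels: np.ndarray,
                  out_dir: str | Path, *, spot_ids=None, slice_ids=None) -> dict[str, Path]:
    """Write embedding and label tables as TSV with deterministic column order.

    ``embeddings.tsv``: spot_id, slice_id, z_0 ... z_{d-1};
    ``labels.tsv``: spot_id, slice_id, domain.
    """
    embeddings = np.asarray(embeddings)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if embeddings.shape[0] != labels.shape[0]:
        raise ValueError(
            f"embeddings has {embeddings.shape[0]} rows but labels has "
            f"{labels.shape[0]} entries"
        )
    m, d = embeddings.shape
    if spot_ids is None:
        spot_ids = [f"spot{i}" for i in range(m)]
    if slice_ids is None:
        slice_ids = ["s0"] * m
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emb = pd.DataFrame(embeddings, columns=[f"z_{j}" for j in range(d)])
    emb.insert(0, "slice_id", list(slice_ids))
    emb.insert(0, "spot_id", list(spot_ids))
    lab = pd.DataFrame({"spot_id": list(spot_ids), "slice_id": list(slice_ids),
                        "domain": labels.astype(int)})
    paths = {"embeddings": out_dir / "embeddings.tsv",
             "labels": out_dir / "labels.tsv"}
    emb.to_csv(paths["embeddings"], sep="\t", index=False, float_format="%.17g")
    lab.to_csv(paths["labels"], sep="\t", index=False)
    return paths


def read_results(out_dir: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back the tables written by :func:`write_results`."""
    out_dir = Path(out_dir)
    emb = pd.read_csv(out_dir / "embeddings.tsv", sep="\t")
    lab = pd.read_csv(out_dir / "labels.tsv", sep="\t")
    zcols = [c for c in emb.columns if c.startswith("z_")]
    return emb[zcols].to_numpy(), lab["domain"].to_numpy()
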