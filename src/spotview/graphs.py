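"""Multi-view neighbor graphs.

Two directed K-nearest-neighbor graphs are built over the spots of each
slice: a spatial graph from Euclidean distances between coordinates and an
expression graph from Pearson correlations between PCA feature rows.  Each
is hybridized with a weighted self-connection, symmetrically degree-
normalized, and, for multi-slice data, assembled block-diagonally so that
no operator entry ever links spots of different slices.

The KNN matrices are kept directed exactly as defined (row i marks the K
neighbors of spot i); the degree used in normalization is the row sum of the
hybridized matrix.  The resulting operator may be mildly asymmetric, which
the graph convolution tolerates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist


@dataclasses.dataclass
class MultiViewGraph:
    """Pair of normalized adjacency operators over all spots."""

    A_spa_norm: sp.csr_matrix
    A_expr_norm: sp.csr_matrix
    k_spatial: int
    k_expr: int
    lambda_self: float

    @property
    def n_spots(self) -> int:
        return self.A_spa_norm.shape[0]


def _knn_from_scores(score: np.ndarray, K: int) -> sp.csr_matrix:
    """Binary directed KNN from a score matrix (higher = closer).

    Self-scores must already be set to -inf.  Ties break toward the lower
    column index for determinism.
    """
    m = score.shape[0]
    # stable argsort on (-score) puts equal scores in index order
    order = np.argsort(-score, axis=1, kind="stable")[:, :K]
    rows = np.repeat(np.arange(m), K)
    A = sp.csr_matrix((np.ones(m * K), (rows, order.ravel())), shape=(m, m))
    return A


def knn_spatial(coords: np.ndarray, K: int) -> sp.csr_matrix:
    """Directed K-nearest-neighbor graph on Euclidean distances."""
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    if K < 1 or K >= m:
        raise ValueError(f"need 1 <= K < m (got K={K}, m={m})")
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    return _knn_from_scores(-D, K)


def knn_expression(X: np.ndarray, K: int) -> sp.csr_matrix:
    """Directed KNN graph on Pearson correlation between feature rows."""
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if K < 1 or K >= m:
        raise ValueError(f"need 1 <= K < m (got K={K}, m={m})")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant feature row(s) {bad.tolist()}: correlation undefined")
    C = np.corrcoef(X)
    np.fill_diagonal(C, -np.inf)
    return _knn_from_scores(C, K)


def hybridize(A: sp.spmatrix, lambda_self: float) -> sp.csr_matrix:
    """Weighted self-connections: ``lam * I + (1 - lam) * A``."""
    if not 0.0 <= lambda_self <= 1.0:
        raise ValueError("lambda_self must lie in [0, 1]")
    m = A.shape[0]
    if A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    out = (lambda_self * sp.identity(m, format="csr")
           + (1.0 - lambda_self) * sp.csr_matrix(A))
    out.eliminate_zeros()
    return out


def normalize_sym(A_hat: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric degree normalization ``D^{-1/2} A_hat D^{-1/2}``.

    Degrees are row sums of ``A_hat``; every row sum must be positive
    (guaranteed whenever the self-connection weight is > 0).
    """
    A_hat = sp.csr_matrix(A_hat)
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("zero row sum: cannot normalize")
    dinv = sp.diags(1.0 / np.sqrt(deg))
    return sp.csr_matrix(dinv @ A_hat @ dinv)


def block_diagonal(graph_list: list[sp.spmatrix]) -> sp.csr_matrix:
    """Assemble per-slice operators into one block-diagonal operator."""
    if len(graph_list) == 0:
        raise ValueError("empty graph list")
    return sp.csr_matrix(sp.block_diag(graph_list, format="csr"))


def build_multiview_graph(coords_list: list[np.ndarray], X: np.ndarray,
                          m_per_slice: np.ndarray, k_spatial: int, k_expr: int,
                          lambda_self: float) -> MultiViewGraph:
    """Per-slice KNN -> hybridize -> normalize -> block-diagonal assembly.

    ``X`` is the pooled feature matrix whose row blocks correspond to the
    slices in order; the expression graph of each slice is built from its
    own rows only.
    """
    offsets = np.concatenate([[0], np.cumsum(m_per_slice)])
    spa_blocks, expr_blocks = [], []
    for l, coords in enumerate(coords_list):
        Xl = X[offsets[l]:offsets[l + 1]]
        spa_blocks.append(
            normalize_sym(hybridize(knn_spatial(coords, k_spatial), lambda_self)))
        expr_blocks.append(
            normalize_sym(hybridize(knn_expression(Xl, k_expr), lambda_self)))
    return MultiViewGraph(
        A_spa_norm=block_diagonal(spa_blocks),
        A_expr_norm=block_diagonal(expr_blocks),
        k_spatial=k_spatial, k_expr=k_expr, lambda_self=lambda_self)


def export_edge_list(A: sp.spmatrix, path: str | Path) -> None:
    """Write a graph as a TSV edge list (i, j, weight), 0-based indices."""
    coo = sp.coo_matrix(A)
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{w:.10g}\n")
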