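"""Count preprocessing: gene filtering, library-size normalization,
log-transform, per-gene standardization, and PCA.

The output :class:`FeatureMatrix` holds the PCA scores the network consumes
plus the per-spot slice index.  For multi-slice input the slices are filtered
jointly (a gene is kept if expressed anywhere), concatenated, and normalized,
standardized, and decomposed as one pooled matrix.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import RawSlice


@dataclasses.dataclass
class FeatureMatrix:
    """PCA feature matrix over all spots of all slices.

    ``X`` is m x n (scores on the first n principal components);
    ``spot_slice_index`` maps each spot to its slice 1..L;
    ``m_per_slice`` gives the spot count of each slice in order.
    """

    X: np.ndarray
    spot_slice_index: np.ndarray
    m_per_slice: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.spot_slice_index = np.asarray(self.spot_slice_index, dtype=int)
        self.m_per_slice = np.asarray(self.m_per_slice, dtype=int)
        if self.X.shape[0] != int(self.m_per_slice.sum()):
            raise ValueError("X row count does not match sum of per-slice counts")
        L = len(self.m_per_slice)
        if self.spot_slice_index.min(initial=1) < 1 or \
                self.spot_slice_index.max(initial=1) > L:
            raise ValueError("spot_slice_index entries must lie in 1..L")

    @property
    def n_slices(self) -> int:
        return len(self.m_per_slice)


def filter_genes(counts_list: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Drop genes with zero total count across all spots of all slices.

    A gene silent in one slice but expressed in another is kept.  Returns the
    filtered matrices and the kept gene indices.
    """
    if len(counts_list) == 0:
        raise ValueError("need at least one slice")
    n_genes = counts_list[0].shape[1]
    for c in counts_list:
        if c.shape[1] != n_genes:
            raise ValueError("all slices must share the same gene set")
    total = np.zeros(n_genes)
    for c in counts_list:
        total += np.asarray(c).sum(axis=0)
    kept = np.flatnonzero(total > 0)
    if kept.size == 0:
        raise ValueError("no expressed genes: every gene has zero total count")
    return [np.asarray(c)[:, kept] for c in counts_list], kept


def normalize_log(Y: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize each spot to ``scale`` and log-transform.

    ``yhat_ij = ln(scale * y_ij / sum_j y_ij + 1)`` — zeros map to zeros and
    the result is invariant to rescaling a spot's whole row.
    """
    Y = np.asarray(Y, dtype=float)
    lib = Y.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"spot(s) {zero.tolist()} have zero library size")
    return np.log1p(scale * Y / lib[:, None])


def standardize(Y_hat: np.ndarray) -> np.ndarray:
    """Per-gene z-score with sample (1/(m-1)) standard deviation.

    Genes with zero variance are mapped to all-zero columns with a warning:
    the z-score is undefined there and such genes carry no signal, but
    dropping them would shift gene indexing.
    """
    Y_hat = np.asarray(Y_hat, dtype=float)
    m = Y_hat.shape[0]
    if m < 2:
        raise ValueError("standardization needs at least 2 spots")
    mu = Y_hat.mean(axis=0)
    sd = Y_hat.std(axis=0, ddof=1)
    const = sd == 0
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} constant gene column(s) set to zero "
            "(zero variance)", stacklevel=2)
    safe_sd = np.where(const, 1.0, sd)
    Z = (Y_hat - mu) / safe_sd
    Z[:, const] = 0.0
    return Z


def pca_reduce(Y_tilde: np.ndarray, n: int) -> np.ndarray:
    """Scores on the first ``n`` principal components, by exact SVD.

    The input is assumed column-centered (it is, post-standardization).
    Component signs are fixed deterministically: the largest-magnitude
    loading of each component is made positive.
    """
    Y_tilde = np.asarray(Y_tilde, dtype=float)
    m, n0 = Y_tilde.shape
    bound = min(m - 1, n0)
    if n > bound:
        raise ValueError(f"n={n} exceeds min(m-1, n_genes)={bound}")
    U, S, Vt = np.linalg.svd(Y_tilde, full_matrices=False)
    U, S, Vt = U[:, :n], S[:n], Vt[:n]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return U * S * flip


def preprocess_slices(slices: list[RawSlice], n_pcs: int) -> FeatureMatrix:
    """Full preprocessing of one or more slices into the network input.

    Filter (jointly) -> concatenate -> per-spot normalize + log -> pooled
    per-gene standardize -> PCA on the pooled matrix.
    """
    filtered, _ = filter_genes([s.counts for s in slices])
    Y = np.vstack(filtered)
    X = pca_reduce(standardize(normalize_log(Y)), n_pcs)
    m_per_slice = np.array([s.n_spots for s in slices])
    idx = np.repeat(np.arange(1, len(slices) + 1), m_per_slice)
    return FeatureMatrix(X=X, spot_slice_index=idx, m_per_slice=m_per_slice)
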