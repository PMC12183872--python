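"""From embeddings to spatial-domain labels.

Domains are called by fitting a K-component Gaussian mixture to the spot
embeddings by EM (full covariances, k-means++ initialization from the run
seed) and taking maximum-posterior assignments, followed by an optional
single synchronous pass of spatial majority-vote refinement: a spot whose
``radius_k`` nearest spatial neighbors (within its own slice) show a strict
majority for one *other* label is reassigned to that label; ties keep the
original label.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.mixture import GaussianMixture


@dataclasses.dataclass
class DomainPartition:
    """Cluster label per spot; labels are 1..K."""

    labels: np.ndarray
    K: int
    slice_index: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.slice_index = np.asarray(self.slice_index, dtype=int)
        if self.labels.shape != self.slice_index.shape:
            raise ValueError("labels and slice_index must align")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.K):
            raise ValueError("labels must lie in 1..K")


def gmm_cluster(Z: np.ndarray, K: int, seed: int,
                slice_index: np.ndarray | None = None,
                covariance_type: str = "diag") -> DomainPartition:
    """K-component Gaussian-mixture EM on the embeddings.

    The default diagonal covariance plays the role of mclust's constrained
    covariance families: with embeddings of width ~64 and on the order of
    10^2 spots per component, per-component full covariances are badly
    overparameterized and EM fits them to noise.  Pass
    ``covariance_type="full"`` to override.  On EM failure the fit is
    retried with a diagonal covariance before raising; deterministic for a
    fixed seed.
    """
    Z = np.asarray(Z, dtype=float)
    m = Z.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if m <= K:
        raise ValueError(f"need more spots than clusters (m={m}, K={K})")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    if slice_index is None:
        slice_index = np.ones(m, dtype=int)
    last_err: Exception | None = None
    attempts = [covariance_type] + (["diag"] if covariance_type != "diag" else [])
    for cov in attempts:
        try:
            gm = GaussianMixture(n_components=K, covariance_type=cov,
                                 init_params="k-means++", n_init=1,
                                 max_iter=300, random_state=seed)
            labels = gm.fit_predict(Z)
            if cov != covariance_type:
                warnings.warn(f"{covariance_type}-covariance EM failed; "
                              "used diagonal", stacklevel=2)
            return DomainPartition(labels=labels + 1, K=K,
                                   slice_index=slice_index)
        except Exception as err:  # singular covariance and kin
            last_err = err
    raise RuntimeError(f"Gaussian-mixture EM failed: {last_err}")


def refine(labels: np.ndarray, coords: np.ndarray, slice_index: np.ndarray,
           radius_k: int) -> np.ndarray:
    """One synchronous pass of strict-majority spatial smoothing per slice."""
    labels = np.asarray(labels, dtype=int)
    coords = np.asarray(coords, dtype=float)
    slice_index = np.asarray(slice_index, dtype=int)
    if radius_k < 1:
        raise ValueError("radius_k must be >= 1")
    out = labels.copy()
    for sl in np.unique(slice_index):
        idx = np.flatnonzero(slice_index == sl)
        if idx.size <= 1:
            continue
        k = min(radius_k, idx.size - 1)
        D = cdist(coords[idx], coords[idx])
        np.fill_diagonal(D, np.inf)
        nn = np.argsort(D, axis=1, kind="stable")[:, :k]
        for local_i, i in enumerate(idx):
            neigh = labels[idx[nn[local_i]]]
            vals, counts = np.unique(neigh, return_counts=True)
            top = counts.max()
            winners = vals[counts == top]
            # strict majority of the consulted neighborhood, single winner,
            # and different from the current label
            if top * 2 > k and winners.size == 1 and winners[0] != labels[i]:
                out[i] = winners[0]
    return out
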