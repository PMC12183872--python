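"""Stochastic training-time augmentation.

Two corruptions are redrawn fresh at every training step: additive Gaussian
feature noise with an independent Bernoulli keep-mask per entry, and edge
masking that zeroes each stored edge of a graph operator independently.
Inference uses no augmentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp


@dataclasses.dataclass
class AugmentSpec:
    """Augmentation parameters: noise scale, feature keep-p, edge keep-p."""

    noise_alpha: float = 0.1
    keep_p: float = 0.9
    edge_keep_p: float = 0.9

    def __post_init__(self) -> None:
        if self.noise_alpha < 0:
            raise ValueError("noise_alpha must be nonnegative")
        for name in ("keep_p", "edge_keep_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def perturb_features(X: np.ndarray, spec: AugmentSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """``x~_ij = b_ij * (x_ij + alpha * eps_ij)`` with fresh iid draws."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    eps = rng.standard_normal(X.shape)
    b = rng.random(X.shape) < spec.keep_p
    return b * (X + spec.noise_alpha * eps)


def feature_noise_draw(shape: tuple[int, int], spec: AugmentSpec,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the (keep-mask, noise) pair used by :func:`perturb_features`.

    Exposed separately so a training step can hold the draw fixed while
    differentiating through the perturbed features.
    """
    eps = rng.standard_normal(shape)
    b = (rng.random(shape) < spec.keep_p).astype(float)
    return b, eps


def corrupt_graph(A_tilde: sp.spmatrix, spec: AugmentSpec,
                  rng: np.random.Generator) -> sp.csr_matrix:
    """Edge masking: each stored nonzero survives with probability edge_keep_p.

    Masking only stored entries is mathematically identical to masking the
    full matrix elementwise, since zeros stay zero either way.
    """
    A = sp.csr_matrix(A_tilde, copy=True)
    keep = rng.random(A.data.shape) < spec.edge_keep_p
    A.data = A.data * keep
    A.eliminate_zeros()
    return A
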