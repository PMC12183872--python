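"""The multi-view graph-convolutional contrastive network.

Architecture, per forward pass:

1. batch correction: ``X_b = X - E @ B1`` (learnable per-slice prompt rows);
2. feature augmentation (training only);
3. per view (spatial / expression), a two-layer GCN with ELU:
   ``Z_v = elu(C(A_v) @ elu(C(A_v) @ X~ @ W11) @ W12)`` where ``C`` is the
   edge-masking corruption, redrawn independently per layer and per view;
4. projection heads: instance head ``H_v = relu(Z_v @ W21) @ W22`` and
   cluster head ``Q_v = softmax(relu(Z_v @ W31) @ W32)`` (shared weights
   across views);
5. attention fusion: per-spot scalar scores ``tanh(Z_v @ W41) @ W42`` are
   softmax-normalized across the two views and broadcast over embedding
   columns, giving ``Z = a_spa * Z_spa + a_expr * Z_expr``;
6. batch restoration ``Z_b = Z + E @ B2`` and a tied-weight decoder
   ``X_hat = relu(Z_b @ W12.T) @ W11.T``.

No layer carries a bias term.  The decoder reuses the encoder tensors, so
gradients accumulate from both paths.  All math is written with
``autograd.numpy`` so the training loop can differentiate the whole chain,
including through the sparse graph operators via a custom matmul primitive.
"""

from __future__ import annotations

import dataclasses

import autograd.numpy as anp
import numpy as np
import scipy.sparse as sp
from autograd.extend import defvjp, primitive


@primitive
def spmm(A, X):
    """Sparse-constant @ dense product; differentiable in the dense factor."""
    return A @ X


defvjp(spmm, None, lambda ans, A, X: lambda g: A.T @ g)


def elu(x):
    return anp.where(x > 0, x, anp.expm1(anp.minimum(x, 0.0)))


def relu(x):
    return anp.maximum(x, 0.0)


def softmax_rows(x):
    shifted = x - anp.max(x, axis=1, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=1, keepdims=True)


@dataclasses.dataclass
class BatchDesign:
    """One-hot spot-by-slice indicator matrix and the slice order."""

    E: np.ndarray
    slice_order: list[str]

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2:
            raise ValueError("E must be 2-D")
        rowsums = self.E.sum(axis=1)
        if not (np.all((self.E == 0) | (self.E == 1)) and np.all(rowsums == 1)):
            raise ValueError("every row of E must be one-hot")

    @classmethod
    def from_slice_index(cls, spot_slice_index: np.ndarray,
                         slice_order: list[str] | None = None) -> "BatchDesign":
        idx = np.asarray(spot_slice_index, dtype=int)
        L = idx.max()
        E = np.zeros((idx.size, L))
        E[np.arange(idx.size), idx - 1] = 1.0
        if slice_order is None:
            slice_order = [f"s{l}" for l in range(L)]
        return cls(E=E, slice_order=slice_order)

    @property
    def n_slices(self) -> int:
        return self.E.shape[1]


@dataclasses.dataclass
class ForwardOutputs:
    """All intermediate tensors of one forward pass."""

    Z_spa: np.ndarray
    Z_expr: np.ndarray
    H_spa: np.ndarray
    H_expr: np.ndarray
    Q_spa: np.ndarray
    Q_expr: np.ndarray
    alpha_spa: np.ndarray
    alpha_expr: np.ndarray
    Z: np.ndarray
    Z_b: np.ndarray
    X_hat: np.ndarray
    X_input: np.ndarray  # the (batch-corrected, augmented) network input


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_params(n_features: int, n_slices: int, config,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform weights; batch prompt embeddings start at zero."""
    n, d1, d, d2, d3, f = (n_features, config.d1, config.d, config.d2,
                           config.d3, config.f)
    Nc = config.n_clusters_proj
    return {
        "W11": glorot(rng, n, d1),
        "W12": glorot(rng, d1, d),
        "W21": glorot(rng, d, d2),
        "W22": glorot(rng, d2, f),
        "W31": glorot(rng, d, d2),
        "W32": glorot(rng, d2, Nc),
        "W41": glorot(rng, d, d3),
        "W42": glorot(rng, d3, 1),
        "B1": np.zeros((n_slices, n)),
        "B2": np.zeros((n_slices, config.d)),
    }


def apply_batch_correction(X, B1, E):
    """``X_b = X - E @ B1``: subtract each spot's slice prompt row."""
    return X - anp.dot(E, B1)


def encode(ops: tuple, X_tilde, W11, W12):
    """Two-layer GCN with ELU; ``ops`` holds the (possibly corrupted)
    operator for each layer."""
    A1, A2 = ops
    h = elu(spmm(A1, anp.dot(X_tilde, W11)))
    return elu(spmm(A2, anp.dot(h, W12)))


def project_instance(Z, W21, W22):
    return anp.dot(relu(anp.dot(Z, W21)), W22)


def project_cluster(Z, W31, W32):
    return softmax_rows(anp.dot(relu(anp.dot(Z, W31)), W32))


def attend(Z_spa, Z_expr, W41, W42):
    """Per-spot scalar attention scores softmaxed across the two views.

    Returns (alpha_spa, alpha_expr) broadcast to the embedding width; the
    two sum to one elementwise and are constant within a row.
    """
    att_spa = anp.dot(anp.tanh(anp.dot(Z_spa, W41)), W42)   # m x 1
    att_expr = anp.dot(anp.tanh(anp.dot(Z_expr, W41)), W42)
    mx = anp.maximum(att_spa, att_expr)
    e_spa = anp.exp(att_spa - mx)
    e_expr = anp.exp(att_expr - mx)
    a_spa = e_spa / (e_spa + e_expr)
    d = Z_spa.shape[1]
    ones = anp.ones((1, d))
    return anp.dot(a_spa, ones), anp.dot(1.0 - a_spa, ones)


def fuse(Z_spa, Z_expr, alpha_spa, alpha_expr):
    return alpha_spa * Z_spa + alpha_expr * Z_expr


def restore_batch(Z, B2, E):
    """``Z_b = Z + E @ B2``: re-attach slice prompts before decoding."""
    return Z + anp.dot(E, B2)


def decode(Z_b, W12, W11):
    """Tied-weight decoder: ``relu(Z_b @ W12.T) @ W11.T``."""
    return anp.dot(relu(anp.dot(Z_b, W12.T)), W11.T)


def forward(params: dict, X: np.ndarray, A_spa: sp.spmatrix,
            A_expr: sp.spmatrix, E: np.ndarray, *,
            noise: tuple | None = None,
            corrupted_ops: dict | None = None) -> ForwardOutputs:
    """Full forward chain.

    ``noise`` is an optional (keep_mask, eps, alpha) triple from the
    augmentation module; ``corrupted_ops`` optionally maps
    ``{"spa": (A1, A2), "expr": (A1, A2)}`` to pre-drawn edge-masked
    operators.  With both omitted the pass is the deterministic inference
    pass (augmentation and corruption are identities).
    """
    Xb = apply_batch_correction(X, params["B1"], E)
    if noise is not None:
        keep, eps, alpha = noise
        X_in = keep * (Xb + alpha * eps)
    else:
        X_in = Xb
    if corrupted_ops is None:
        corrupted_ops = {"spa": (A_spa, A_spa), "expr": (A_expr, A_expr)}
    Z_spa = encode(corrupted_ops["spa"], X_in, params["W11"], params["W12"])
    Z_expr = encode(corrupted_ops["expr"], X_in, params["W11"], params["W12"])
    H_spa = project_instance(Z_spa, params["W21"], params["W22"])
    H_expr = project_instance(Z_expr, params["W21"], params["W22"])
    Q_spa = project_cluster(Z_spa, params["W31"], params["W32"])
    Q_expr = project_cluster(Z_expr, params["W31"], params["W32"])
    a_spa, a_expr = attend(Z_spa, Z_expr, params["W41"], params["W42"])
    Z = fuse(Z_spa, Z_expr, a_spa, a_expr)
    Z_b = restore_batch(Z, params["B2"], E)
    X_hat = decode(Z_b, params["W12"], params["W11"])
    return ForwardOutputs(Z_spa=Z_spa, Z_expr=Z_expr, H_spa=H_spa,
                          H_expr=H_expr, Q_spa=Q_spa, Q_expr=Q_expr,
                          alpha_spa=a_spa, alpha_expr=a_expr, Z=Z, Z_b=Z_b,
                          X_hat=X_hat, X_input=X_in)


def save_checkpoint(params: dict, config, path) -> None:
    """One archive holding every parameter tensor plus the run config."""
    import json

    from dataclasses import asdict

    np.savez(path, __config__=json.dumps(asdict(config)),
             **{k: np.asarray(v) for k, v in params.items()})


def load_checkpoint(path):
    import json

    from .config import RunConfig

    with np.load(path, allow_pickle=False) as data:
        config = RunConfig(**json.loads(str(data["__config__"])))
        params = {k: data[k] for k in data.files if k != "__config__"}
    return params, config
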