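"""Training objectives.

Three terms are combined: a mean-squared reconstruction loss, an
instance-level contrastive loss aligning each spot's projection across the
two views (cross-view negatives only — same-view negatives are deliberately
omitted because enforced dissimilarity between neighboring spots would fight
the smoothing of the graph convolution), and a cluster-level contrastive
loss over the pseudo-cluster assignment *columns* with an entropy
regularizer that penalizes collapse onto few clusters.  Total objective:

    L = L_rec + (L_cls_spa + L_cls_expr) + kappa * L_ins

The cluster loss denominators include the cross-view positive, all
cross-view k != j columns, and same-view k != j columns — an asymmetry
relative to the instance loss that is intentional and kept as defined.

Slow scalar-loop reference implementations for every term live in
:mod:`spotview.losses_reference` for testing.
"""

from __future__ import annotations

import dataclasses

import autograd.numpy as anp
import numpy as np

_EPS = 1e-8  # norm floor for gradient stability; exact-zero rows still raise


@dataclasses.dataclass
class LossBreakdown:
    """Per-component loss values of one training step."""

    L_rec: float
    L_ins: float
    L_cls_spa: float
    L_cls_expr: float
    L_reg_spa: float
    L_reg_expr: float
    kappa: float

    @property
    def total(self) -> float:
        return self.L_rec + self.L_cls_spa + self.L_cls_expr + self.kappa * self.L_ins


def _cosine_matrix(A, B):
    """Pairwise cosine similarity between rows of A and rows of B.

    The tiny additive term inside the square root keeps the gradient
    finite at an exactly-zero row (it perturbs nonzero norms at the 1e-16
    relative level, far below the 1e-8 norm floor).
    """
    na = anp.sqrt(anp.sum(A * A, axis=1) + _EPS ** 2) + _EPS
    nb = anp.sqrt(anp.sum(B * B, axis=1) + _EPS ** 2) + _EPS
    return anp.dot(A / na[:, None], (B / nb[:, None]).T)


def _check_rows_nonzero(H, name):
    if isinstance(H, np.ndarray):
        zero = np.flatnonzero(np.linalg.norm(H, axis=1) == 0)
        if zero.size:
            raise ValueError(f"{name}: zero-norm row(s) at spot(s) {zero.tolist()}")


def instance_loss(H_spa, H_expr, tau_ins: float):
    """Symmetric cross-view InfoNCE over spots, cosine similarity.

    For anchor i in one view the positive is spot i in the other view and
    the negatives are the other spots of the other view only; the two
    directions are each averaged over spots and summed.
    """
    if tau_ins <= 0:
        raise ValueError("tau_ins must be > 0")
    _check_rows_nonzero(H_spa, "H_spa")
    _check_rows_nonzero(H_expr, "H_expr")
    S = _cosine_matrix(H_spa, H_expr) / tau_ins       # m x m
    mx1 = anp.max(S, axis=1, keepdims=True)
    lse1 = anp.log(anp.sum(anp.exp(S - mx1), axis=1)) + mx1[:, 0]
    mx2 = anp.max(S, axis=0, keepdims=True)
    lse2 = anp.log(anp.sum(anp.exp(S - mx2), axis=0)) + mx2[0, :]
    diag = anp.diag(S)
    return anp.mean(lse1 - diag) + anp.mean(lse2 - diag)


def cluster_loss(Q_spa, Q_expr, tau_cls: float):
    """Cluster-column contrastive loss plus entropy regularizers.

    The contrast runs over the pseudo-cluster columns q_j: for anchor
    column j of one view the positive is column j of the other view, the
    negatives the other columns of both views.  The regularizer is
    ``sum_j pi_j log pi_j`` with pi_j the normalized column masses (its
    minimum -log N_c is attained at uniform cluster usage).

    Returns (L_cls_spa, L_cls_expr, L_reg_spa, L_reg_expr), where the
    ``L_cls_*`` already include their regularizer.
    """
    if tau_cls <= 0:
        raise ValueError("tau_cls must be > 0")
    for Q, name in ((Q_spa, "Q_spa"), (Q_expr, "Q_expr")):
        if isinstance(Q, np.ndarray):
            zero = np.flatnonzero(np.linalg.norm(Q, axis=0) == 0)
            if zero.size:
                raise ValueError(f"{name}: all-zero column(s) {zero.tolist()}")
    Nc = Q_spa.shape[1]
    Cse = _cosine_matrix(Q_spa.T, Q_expr.T) / tau_cls   # Nc x Nc, spa rows
    Css = _cosine_matrix(Q_spa.T, Q_spa.T) / tau_cls
    Cee = _cosine_matrix(Q_expr.T, Q_expr.T) / tau_cls
    off = 1.0 - anp.eye(Nc)

    def one_direction(C_cross, C_same):
        pos = anp.diag(C_cross)
        denom = anp.sum(anp.exp(C_cross), axis=1) + \
            anp.sum(anp.exp(C_same) * off, axis=1)
        return -anp.mean(pos - anp.log(denom))

    reg_spa = _entropy_reg(Q_spa)
    reg_expr = _entropy_reg(Q_expr)
    L_spa = one_direction(Cse, Css) + reg_spa
    L_expr = one_direction(Cse.T, Cee) + reg_expr
    return L_spa, L_expr, reg_spa, reg_expr


def _entropy_reg(Q):
    pi = anp.sum(Q, axis=0)
    pi = pi / anp.sum(pi)
    # pi * log(pi) with the 0 * log 0 = 0 convention, exact at pi = 1
    safe = anp.where(pi > 0, pi, 1.0)
    return anp.sum(safe * anp.log(safe))


def recon_loss(X, X_hat):
    """Mean squared reconstruction error over all entries."""
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    diff = X - X_hat
    return anp.sum(diff * diff) / (X.shape[0] * X.shape[1])


def total_loss(parts: LossBreakdown) -> float:
    """Weighted sum ``L_rec + L_cls + kappa * L_ins``."""
    return parts.total
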