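"""Scalar-loop reference implementations of the training losses.

These follow the loss definitions term by term with explicit Python loops
and no vectorization tricks, and exist solely as independent oracles for
the fast implementations in :mod:`spotview.losses`.  Do not use them for
training; they are O(m^2 f) with Python-loop constants.
"""

from __future__ import annotations

import math

import numpy as np


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.dot(u, v) / ((np.linalg.norm(u) + 1e-8)
                                 * (np.linalg.norm(v) + 1e-8)))


def instance_loss_reference(H_spa: np.ndarray, H_expr: np.ndarray,
                            tau: float) -> float:
    m = H_spa.shape[0]
    total = 0.0
    for anchor, other in ((H_spa, H_expr), (H_expr, H_spa)):
        acc = 0.0
        for i in range(m):
            num = math.exp(cosine(anchor[i], other[i]) / tau)
            den = sum(math.exp(cosine(anchor[i], other[k]) / tau)
                      for k in range(m))
            acc += -math.log(num / den)
        total += acc / m
    return total


def entropy_reg_reference(Q: np.ndarray) -> float:
    col = Q.sum(axis=0)
    pi = col / col.sum()
    return float(sum(p * math.log(p) for p in pi if p > 0))


def cluster_loss_reference(Q_spa: np.ndarray, Q_expr: np.ndarray,
                           tau: float) -> tuple[float, float, float, float]:
    Nc = Q_spa.shape[1]

    def one_direction(Qa: np.ndarray, Qb: np.ndarray) -> float:
        acc = 0.0
        for j in range(Nc):
            num = math.exp(cosine(Qa[:, j], Qb[:, j]) / tau)
            den = sum(math.exp(cosine(Qa[:, j], Qb[:, k]) / tau)
                      for k in range(Nc))
            den += sum(math.exp(cosine(Qa[:, j], Qa[:, k]) / tau)
                       for k in range(Nc) if k != j)
            acc += -math.log(num / den)
        return acc / Nc

    reg_spa = entropy_reg_reference(Q_spa)
    reg_expr = entropy_reg_reference(Q_expr)
    return (one_direction(Q_spa, Q_expr) + reg_spa,
            one_direction(Q_expr, Q_spa) + reg_expr,
            reg_spa, reg_expr)


def recon_loss_reference(X: np.ndarray, X_hat: np.ndarray) -> float:
    m, n = X.shape
    acc = 0.0
    for i in range(m):
        for j in range(n):
            acc += (X[i, j] - X_hat[i, j]) ** 2
    return acc / (m * n)
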