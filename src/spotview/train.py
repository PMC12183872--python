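"""Full-graph training loop.

One Adam step per epoch on the whole graph: fresh augmentation draws, a
forward pass, the (ablation-dependent) total loss, and a parameter update.
A single numpy Generator seeded from the run config drives parameter
initialization and every augmentation draw, so a run is reproducible
bit-for-bit from its seed.

Ablation modes are loss-term switches, not separate code paths:
``no_instance`` drops the instance term (kappa = 0), ``no_cluster`` drops
the cluster term, ``no_both`` trains the autoencoder alone, and
``no_prompting`` freezes both batch prompt matrices at zero.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from autograd import value_and_grad

from . import losses, network
from .augment import AugmentSpec, corrupt_graph, feature_noise_draw
from .config import RunConfig
from .graphs import MultiViewGraph
from .network import BatchDesign, forward, init_params
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

ABLATION_MODES = ("full", "no_instance", "no_cluster", "no_both", "no_prompting")


@dataclasses.dataclass
class TrainLog:
    """Per-epoch loss components plus run provenance."""

    history: list[losses.LossBreakdown]
    seed: int
    ablation: str

    @property
    def epochs_run(self) -> int:
        return len(self.history)


def _unbox(x) -> float:
    while hasattr(x, "_value"):
        x = x._value
    return float(x)


class AdamOptimizer:
    """Plain Adam over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, frozen: set[str] = frozenset()):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k in params:
            if k in frozen:
                continue
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
        return params


def fit(features: FeatureMatrix, graphs: MultiViewGraph, design: BatchDesign,
        config: RunConfig, ablation: str = "full"
        ) -> tuple[dict, TrainLog]:
    """Train the network; returns (final parameters, per-epoch loss log)."""
    if ablation not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode '{ablation}'; "
                         f"choose from {ABLATION_MODES}")
    rng = np.random.default_rng(config.seed)
    X = features.X
    m, n = X.shape
    L = design.n_slices
    params = init_params(n, L, config, rng)
    opt = AdamOptimizer(params, config.learning_rate)

    frozen: set[str] = set()
    if ablation == "no_prompting" or L == 1:
        frozen |= {"B1", "B2"}  # prompts stay at their zero initialization
    else:
        # The input-side prompts are set by their moment condition -- each
        # slice's feature-mean deviation from the global mean, the natural
        # estimator of an additive slice effect -- and then held fixed.
        # Nothing in the objective prefers batch-free embeddings: left to
        # gradient descent, reconstruction happily drives B1 back to zero
        # and routes the slice offsets into Z instead.  Fixing B1 at the
        # moment estimate means the encoder never sees the offsets, while
        # the output-side prompts B2 train freely to restore them for the
        # decoder.
        slice_means = (design.E.T @ X) / design.E.sum(axis=0)[:, None]
        params["B1"] = slice_means - X.mean(axis=0)
        frozen |= {"B1"}

    aug = AugmentSpec(noise_alpha=config.noise_alpha, keep_p=config.mask_p,
                      edge_keep_p=config.edge_keep_p)
    A_spa = graphs.A_spa_norm.tocsr()
    A_expr = graphs.A_expr_norm.tocsr()
    E = design.E
    kappa = 0.0 if ablation in ("no_instance", "no_both") else config.kappa
    use_cluster = ablation not in ("no_cluster", "no_both")
    use_instance = ablation not in ("no_instance", "no_both")

    history: list[losses.LossBreakdown] = []
    for epoch in range(config.epochs):
        keep, eps = feature_noise_draw((m, n), aug, rng)
        ops = {
            "spa": (corrupt_graph(A_spa, aug, rng), corrupt_graph(A_spa, aug, rng)),
            "expr": (corrupt_graph(A_expr, aug, rng), corrupt_graph(A_expr, aug, rng)),
        }
        parts_box: dict[str, float] = {}

        def objective(p):
            out = forward(p, X, A_spa, A_expr, E,
                          noise=(keep, eps, aug.noise_alpha),
                          corrupted_ops=ops)
            L_rec = losses.recon_loss(X, out.X_hat)
            total = L_rec
            L_ins = 0.0
            L_cs = L_ce = rs = re = 0.0
            if use_instance:
                L_ins = losses.instance_loss(out.H_spa, out.H_expr,
                                             config.tau_ins)
                total = total + kappa * L_ins
            if use_cluster:
                L_cs, L_ce, rs, re = losses.cluster_loss(
                    out.Q_spa, out.Q_expr, config.tau_cls)
                total = total + L_cs + L_ce
            parts_box.update(L_rec=_unbox(L_rec), L_ins=_unbox(L_ins),
                             L_cls_spa=_unbox(L_cs), L_cls_expr=_unbox(L_ce),
                             L_reg_spa=_unbox(rs), L_reg_expr=_unbox(re))
            return total

        total_val, grads = value_and_grad(objective)(params)
        if not np.isfinite(total_val):
            bad = [k for k, v in parts_box.items() if not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: component(s) {bad or ['total']}")
        params = opt.step(params, grads, frozen=frozen)
        breakdown = losses.LossBreakdown(kappa=kappa, **parts_box)
        history.append(breakdown)
        if epoch % 50 == 0 or epoch == config.epochs - 1:
            logger.info(
                "epoch %d: total=%.5f rec=%.5f cls=%.5f ins=%.5f",
                epoch, breakdown.total, breakdown.L_rec,
                breakdown.L_cls_spa + breakdown.L_cls_expr, breakdown.L_ins)
    return params, TrainLog(history=history, seed=config.seed, ablation=ablation)


def extract_embeddings(params: dict, features: FeatureMatrix,
                       graphs: MultiViewGraph, design: BatchDesign) -> np.ndarray:
    """Deterministic inference pass; returns the fused bottleneck embeddings.

    Augmentation and edge corruption are disabled; the slice prompts are
    subtracted from the input but *not* re-added, so the embeddings are the
    batch-corrected representations used for clustering.
    """
    out = forward(params, features.X, graphs.A_spa_norm.tocsr(),
                  graphs.A_expr_norm.tocsr(), design.E)
    return np.asarray(out.Z)
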