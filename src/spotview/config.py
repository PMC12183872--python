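"""Run configuration for the full pipeline.

All hyperparameters of the model live in one :class:`RunConfig` so that a run
is fully described by (data, config, seed).  Every field has a default, so the
command line can run end-to-end on simulated fixtures with zero flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Hyperparameters of the multi-view contrastive model.

    Parameters
    ----------
    n_pcs
        Number of principal components retained from the standardized
        log-normalized expression; this is the width of the network input.
    k_spatial, k_expr
        Neighbor counts of the spatial and expression KNN graphs.  The
        default of 6 matches the physical neighbor count of hexagonal
        Visium arrays.
    lambda_self
        Self-connection weight ``lam`` in the hybrid adjacency
        ``lam*I + (1-lam)*A``; 0.3 by default.
    noise_alpha, mask_p, edge_keep_p
        Augmentation controls: Gaussian noise scale, Bernoulli feature
        keep-probability, and Bernoulli edge keep-probability.
    d1, d, d2, d3, f
        Layer widths: encoder hidden, embedding (bottleneck), projection
        hidden, attention hidden, and instance-projection output.
    n_pseudo
        Number of pseudo-cluster columns of the cluster projection head;
        ``None`` means "use ``n_domains``".
    tau_ins, tau_cls
        Temperatures of the instance and cluster contrastive losses.
    kappa
        Weight on the instance contrastive loss in the total objective.
    n_domains
        Number of spatial domains K requested from the final clustering.
    refinement_radius
        Number of spatial nearest neighbors consulted by the majority-vote
        label refinement.
    """

    n_pcs: int = 50
    k_spatial: int = 6
    k_expr: int = 6
    lambda_self: float = 0.3
    noise_alpha: float = 0.1
    mask_p: float = 0.9
    edge_keep_p: float = 0.9
    d1: int = 128
    d: int = 64
    d2: int = 64
    d3: int = 32
    f: int = 32
    n_pseudo: int | None = None
    tau_ins: float = 0.5
    tau_cls: float = 1.0
    kappa: float = 1.0
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    n_domains: int = 5
    refinement_radius: int = 6
    refine: bool = True

    def __post_init__(self) -> None:
        for name in ("mask_p", "edge_keep_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.lambda_self <= 1.0:
            raise ValueError(f"lambda_self={self.lambda_self} must lie in [0, 1]")
        if self.noise_alpha < 0:
            raise ValueError("noise_alpha must be nonnegative")
        for name in ("n_pcs", "k_spatial", "k_expr", "d1", "d", "d2", "d3", "f",
                     "n_domains", "refinement_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_pseudo is not None and self.n_pseudo < 1:
            raise ValueError("n_pseudo must be >= 1")
        for name in ("tau_ins", "tau_cls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")

    @property
    def n_clusters_proj(self) -> int:
        """Width of the cluster projection head (defaults to ``n_domains``)."""
        return self.n_domains if self.n_pseudo is None else self.n_pseudo

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
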