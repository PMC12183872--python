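"""Model / Results surface.

:class:`SpatialDomainModel` is constructed from one or more raw slices and a
:class:`~spotview.config.RunConfig`; construction performs preprocessing and
multi-view graph building, ``fit()`` trains the network and returns a
:class:`SpatialDomainResults` carrying the learned parameters, the loss
trajectory, the batch-corrected spot embeddings, and clustering/evaluation
methods.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import evaluate, io, train
from .cluster import DomainPartition, gmm_cluster, refine
from .config import RunConfig
from .graphs import MultiViewGraph, build_multiview_graph, knn_spatial
from .io import RawSlice
from .network import BatchDesign
from .preprocess import FeatureMatrix, preprocess_slices


class SpatialDomainModel:
    """Multi-view graph contrastive model over one or more SRT slices."""

    def __init__(self, slices: list[RawSlice], config: RunConfig | None = None):
        if len(slices) == 0:
            raise ValueError("need at least one slice")
        self.config = config or RunConfig()
        self.slices = list(slices)
        self.features: FeatureMatrix = preprocess_slices(
            self.slices, self.config.n_pcs)
        self.graphs: MultiViewGraph = build_multiview_graph(
            [s.coords for s in self.slices], self.features.X,
            self.features.m_per_slice, self.config.k_spatial,
            self.config.k_expr, self.config.lambda_self)
        self.design = BatchDesign.from_slice_index(
            self.features.spot_slice_index,
            slice_order=[s.slice_id for s in self.slices])
        self.coords = np.vstack([s.coords for s in self.slices])

    @classmethod
    def from_files(cls, matrix_paths: list[str], coords_paths: list[str],
                   config: RunConfig | None = None) -> "SpatialDomainModel":
        """Build from per-slice (matrix, coords) file pairs, in CLI order.

        The file order defines the slice (batch) index of every spot.
        """
        if len(matrix_paths) != len(coords_paths):
            raise ValueError("one coords file per matrix file required")
        slices = [io.read_slice(mp, cp, slice_id=f"s{l}")
                  for l, (mp, cp) in enumerate(zip(matrix_paths, coords_paths))]
        return cls(slices, config)

    @classmethod
    def from_anndata(cls, adatas: list, config: RunConfig | None = None
                     ) -> "SpatialDomainModel":
        """Build from AnnData objects with counts in X and obsm['spatial']."""
        import scipy.sparse as sp

        slices = []
        for l, ad in enumerate(adatas):
            X = ad.X
            counts = np.asarray(X.todense() if sp.issparse(X) else X)
            coords = np.asarray(ad.obsm["spatial"], dtype=float)[:, :2]
            slices.append(RawSlice(counts=counts, coords=coords,
                                   slice_id=str(ad.uns.get("slice_id", f"s{l}")),
                                   gene_names=list(map(str, ad.var_names))))
        return cls(slices, config)

    def fit(self, ablation: str = "full") -> "SpatialDomainResults":
        """Train and return the fitted results object."""
        params, log = train.fit(self.features, self.graphs, self.design,
                                self.config, ablation=ablation)
        Z = train.extract_embeddings(params, self.features, self.graphs,
                                     self.design)
        return SpatialDomainResults(model=self, params=params, train_log=log,
                                    embeddings=Z)


@dataclasses.dataclass
class SpatialDomainResults:
    """Fitted state: parameters, loss history, embeddings, and diagnostics."""

    model: SpatialDomainModel
    params: dict
    train_log: train.TrainLog
    embeddings: np.ndarray

    def cluster(self, n_domains: int | None = None,
                refine_labels: bool | None = None) -> DomainPartition:
        """Gaussian-mixture domains (optionally spatially refined)."""
        cfg = self.model.config
        K = n_domains or cfg.n_domains
        do_refine = cfg.refine if refine_labels is None else refine_labels
        part = gmm_cluster(self.embeddings, K, seed=cfg.seed,
                           slice_index=self.model.features.spot_slice_index)
        labels = part.labels
        if do_refine:
            labels = refine(labels, self.model.coords, part.slice_index,
                            cfg.refinement_radius)
        return DomainPartition(labels=labels, K=K, slice_index=part.slice_index)

    def evaluate(self, truth: np.ndarray,
                 partition: DomainPartition | None = None
                 ) -> evaluate.MetricReport:
        """Metric report of a partition (default: ``self.cluster()``) vs truth."""
        part = partition or self.cluster()
        graph = knn_spatial(self.model.coords, self.model.config.k_spatial)
        return evaluate.metric_report(part.labels, truth, self.embeddings, graph)

    def save(self, out_dir: str | Path,
             partition: DomainPartition | None = None) -> dict[str, Path]:
        """Write embeddings, labels, and run metadata as TSV/YAML."""
        part = partition or self.cluster()
        m_per = self.model.features.m_per_slice
        slice_ids = np.repeat([s.slice_id for s in self.model.slices], m_per)
        paths = io.write_results(self.embeddings, part.labels, out_dir,
                                 slice_ids=slice_ids)
        cfg_path = Path(out_dir) / "run_config.yaml"
        self.model.config.to_yaml(cfg_path)
        paths["config"] = cfg_path
        return paths

    def plot_domains(self, partition: DomainPartition | None = None, ax=None):
        """Scatter the spots colored by domain (one panel, slices offset)."""
        import matplotlib.pyplot as plt

        part = partition or self.cluster()
        coords = self.model.coords.copy()
        # offset slices horizontally so they do not overplot
        offsets = np.concatenate([[0], np.cumsum(self.model.features.m_per_slice)])
        span = coords[:, 0].max() - coords[:, 0].min() + 2
        for l in range(self.model.features.n_slices):
            coords[offsets[l]:offsets[l + 1], 0] += l * span
        if ax is None:
            _, ax = plt.subplots(figsize=(4 * self.model.features.n_slices, 4))
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=part.labels, s=12,
                        cmap="tab10")
        ax.set_aspect("equal")
        ax.set_xlabel("x (slices offset)")
        ax.set_ylabel("y")
        plt.colorbar(sc, ax=ax, label="domain")
        return ax

    def summary(self) -> str:
        """Human-readable fit summary table."""
        cfg = self.model.config
        log = self.train_log
        first = log.history[0].total if log.history else float("nan")
        last = log.history[-1].total if log.history else float("nan")
        rows = [
            ("slices", self.model.features.n_slices),
            ("spots", self.embeddings.shape[0]),
            ("embedding dim", self.embeddings.shape[1]),
            ("epochs", log.epochs_run),
            ("ablation", log.ablation),
            ("seed", log.seed),
            ("loss (epoch 1)", f"{first:.5f}"),
            ("loss (final)", f"{last:.5f}"),
        ]
        if log.history:
            h = log.history[-1]
            rows += [
                ("final reconstruction loss", f"{h.L_rec:.5f}"),
                ("final cluster loss", f"{h.L_cls_spa + h.L_cls_expr:.5f}"),
                ("final instance loss", f"{h.L_ins:.5f}"),
            ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Spatial domain model fit",
                 "=" * (width + 22)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        lines.append(f"{'n_domains (K)':<{width}}  {cfg.n_domains}")
        return "\n".join(lines)
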