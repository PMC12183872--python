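"""Synthetic multi-slice SRT generator with known ground truth.

Spots sit on a regular 2-D lattice partitioned into contiguous horizontal
bands (one band block per domain), mimicking layered tissue such as cortex.
Each domain has a disjoint set of marker genes whose log-mean is raised by
``signal_strength``; counts are Poisson draws from

    mean_ijl = base_mean * exp(signal * 1[j marker of domain(i)] + shift_jl)

followed by independent zeroing with probability ``dropout_p``
(zero-inflation).  ``shift_jl ~ N(0, batch_shift_sd)`` is an additive
per-gene log-scale location shift drawn once per slice — the standard
batch-effect model.  The domain layout is identical across slices.

Everything is reproducible from the spec seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cluster import gmm_cluster
from .evaluate import ari
from .io import RawSlice
from .preprocess import pca_reduce, standardize


@dataclasses.dataclass
class SynthSpec:
    grid_shape: tuple[int, int] = (20, 25)
    n_domains: int = 5
    n_genes: int = 200
    n_markers_per_domain: int = 20
    signal_strength: float = 1.5
    base_mean: float = 1.0
    batch_shift_sd: float = 0.0
    dropout_p: float = 0.3
    n_slices: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols < self.n_domains or rows < self.n_domains:
            raise ValueError("grid too small for the requested domain count")
        if self.n_markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError("dropout_p must lie in [0, 1]")
        for name in ("signal_strength", "base_mean", "batch_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def presets() -> dict[str, SynthSpec]:
    """Named study conditions.

    ``easy``: one 20x25 slice (500 spots), 5 banded domains, 200 genes with
    20 markers per domain at log-fold effect 1.5, no batch effect.
    ``batchy``: two such slices with per-gene slice shifts of s.d. 1.0.
    """
    return {
        "easy": SynthSpec(),
        "batchy": SynthSpec(n_slices=2, batch_shift_sd=1.0),
    }


def _domain_layout(rows: int, cols: int, n_domains: int) -> np.ndarray:
    """Row-band partition: contiguous blocks of rows, one per domain."""
    row_domain = np.repeat(np.arange(1, n_domains + 1),
                           [len(b) for b in np.array_split(np.arange(rows),
                                                           n_domains)])
    return np.repeat(row_domain, cols)


def mean_matrix(spec: SynthSpec, shifts: np.ndarray) -> np.ndarray:
    """Noise-free per-slice mean matrices stacked over slices (m_total x genes)."""
    rows, cols = spec.grid_shape
    domains = _domain_layout(rows, cols, spec.n_domains)
    marker_of = np.full(spec.n_genes, 0)
    for k in range(spec.n_domains):
        lo = k * spec.n_markers_per_domain
        marker_of[lo:lo + spec.n_markers_per_domain] = k + 1
    is_marker = (marker_of[None, :] == domains[:, None]).astype(float)
    blocks = []
    for l in range(spec.n_slices):
        logmean = (np.log(spec.base_mean)
                   + spec.signal_strength * is_marker
                   + shifts[l][None, :])
        blocks.append(np.exp(logmean))
    return np.vstack(blocks)


def generate(spec: SynthSpec) -> tuple[list[RawSlice], np.ndarray, np.ndarray]:
    """Simulate the dataset; returns (slices, domain labels, batch labels).

    Domain labels (1..n_domains) and batch labels (1..n_slices) cover the
    concatenated spots of all slices in order.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    m = rows * cols
    domains = _domain_layout(rows, cols, spec.n_domains)
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    shifts = rng.normal(0.0, spec.batch_shift_sd,
                        size=(spec.n_slices, spec.n_genes))
    means = mean_matrix(spec, shifts)
    slices = []
    for l in range(spec.n_slices):
        mu = means[l * m:(l + 1) * m]
        counts = rng.poisson(mu)
        keep = rng.random(counts.shape) >= spec.dropout_p
        counts = counts * keep
        # a spot losing all counts to dropout cannot be normalized; give it
        # one count in a random gene (rare at realistic settings)
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        for i in empty:
            counts[i, rng.integers(spec.n_genes)] = 1
        slices.append(RawSlice(counts=counts, coords=coords.copy(),
                               slice_id=f"s{l}",
                               gene_names=[f"g{j}" for j in range(spec.n_genes)]))
    domain_labels = np.tile(domains, spec.n_slices)
    batch_labels = np.repeat(np.arange(1, spec.n_slices + 1), m)
    return slices, domain_labels, batch_labels


def oracle_separability(spec: SynthSpec) -> float:
    """Upper-bound recovery reference: cluster the noise-free means.

    ARI against truth of Gaussian-mixture clustering applied to the PCA of
    the standardized noise-free mean matrix (batch shifts included).
    """
    rng = np.random.default_rng(spec.seed)
    shifts = rng.normal(0.0, spec.batch_shift_sd,
                        size=(spec.n_slices, spec.n_genes))
    means = mean_matrix(spec, shifts)
    rows, cols = spec.grid_shape
    domains = np.tile(_domain_layout(rows, cols, spec.n_domains), spec.n_slices)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns when signal = 0
        Y = standardize(np.log1p(means))
    n = min(20, means.shape[0] - 1, means.shape[1])
    X = pca_reduce(Y, n)
    part = gmm_cluster(X, spec.n_domains, seed=spec.seed)
    return ari(part.labels, domains)
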