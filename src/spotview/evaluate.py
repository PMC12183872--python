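"""Clustering evaluation and dataset-difficulty statistics.

External metrics (adjusted Rand index, normalized mutual information with
arithmetic-mean normalization) compare predicted domains with annotations;
internal metrics (mean silhouette, Calinski-Harabasz) score cluster
structure in the embedding space without labels.  Two dataset statistics
summarize how hard a labeling is: label smoothness (LS), the fraction of
directed spatial-KNN edges whose endpoints share a label, and label
entropy (LE), the Shannon entropy of the label proportions (natural log).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from sklearn import metrics as skm


@dataclasses.dataclass
class MetricReport:
    ari: float
    nmi: float
    silhouette: float
    calinski_harabasz: float
    label_smoothness: float
    label_entropy: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _check_lengths(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 2:
        raise ValueError("need at least 2 spots")
    return pred, truth


def ari(pred, truth) -> float:
    """Adjusted Rand index (permutation-model expectation)."""
    pred, truth = _check_lengths(pred, truth)
    return float(skm.adjusted_rand_score(truth, pred))


def nmi(pred, truth) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    pred, truth = _check_lengths(pred, truth)
    return float(skm.normalized_mutual_info_score(truth, pred,
                                                  average_method="arithmetic"))


def silhouette(Z, labels) -> float:
    """Mean Euclidean silhouette over spots."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    return float(skm.silhouette_score(np.asarray(Z, dtype=float), labels))


def calinski_harabasz(Z, labels) -> float:
    """Between/within dispersion ratio scaled by (m-K)/(K-1)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("Calinski-Harabasz needs >= 2 clusters")
    return float(skm.calinski_harabasz_score(np.asarray(Z, dtype=float), labels))


def label_smoothness(labels, spatial_graph) -> float:
    """Fraction of directed graph edges whose endpoints share a label."""
    labels = np.asarray(labels)
    A = sp.coo_matrix(spatial_graph)
    if A.nnz == 0:
        raise ValueError("graph has no edges")
    same = labels[A.row] == labels[A.col]
    return float(np.mean(same))


def label_entropy(labels) -> float:
    """Shannon entropy (natural log) of the label proportions."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def metric_report(pred, truth, Z, spatial_graph) -> MetricReport:
    """All metrics in one report, computed on pooled spots."""
    return MetricReport(
        ari=ari(pred, truth),
        nmi=nmi(pred, truth),
        silhouette=silhouette(Z, pred),
        calinski_harabasz=calinski_harabasz(Z, pred),
        label_smoothness=label_smoothness(pred, spatial_graph),
        label_entropy=label_entropy(pred),
    )
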