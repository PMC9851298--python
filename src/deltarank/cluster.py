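"""Clustering backends and external evaluation indices.

Cells (columns of a feature matrix) are partitioned with standard backends
— k-means, Ward hierarchical, spectral — and predicted partitions are
scored against known cell types with three external indices:

* ARI, the adjusted Rand index (pair-counting, chance-corrected, in
  [-1, 1]);
* NMI, mutual information normalized by the arithmetic mean of the two
  label entropies (in [0, 1]; defined as 1 when both partitions are
  single-cluster);
* purity, the fraction of cells assigned to the majority true class of
  their predicted cluster (in [0, 1]; degenerate all-singleton
  predictions score 1, a known inflation).

The backends are evaluation machinery, not a contribution: externally
produced label files can be scored the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .errors import ValidationError

_METHODS = ("kmeans", "hierarchical", "spectral")


@dataclass
class Partition:
    """Cluster assignment of a set of cells."""

    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.cell_ids) != self.labels.size:
            raise ValidationError("cell_ids and labels differ in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell identifiers")

    @property
    def k(self) -> int:
        return len(set(self.labels.tolist()))


def cluster(
    matrix: np.ndarray,
    method: str = "kmeans",
    k: int = 2,
    seed: int = 0,
    cell_ids: list[str] | None = None,
) -> Partition:
    """Partition cells (columns) into k groups in feature space.

    Deterministic under a fixed seed. Hierarchical uses Ward linkage with
    Euclidean distance; spectral uses an RBF affinity with k-means label
    assignment.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("expected a features x cells matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValidationError("feature matrix must be finite")
    n = matrix.shape[1]
    if not 1 <= k <= n:
        raise ValidationError(f"k = {k} must lie in [1, n = {n}]")
    X = matrix.T  # observations = cells
    if method == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    elif method == "hierarchical":
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    elif method == "spectral":
        labels = SpectralClustering(
            n_clusters=k, random_state=seed, assign_labels="kmeans"
        ).fit_predict(X)
    else:
        raise ValidationError(f"unknown method {method!r}; pick from {_METHODS}")
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
    return Partition(cell_ids=list(ids), labels=labels)


def _aligned_labels(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    """Label arrays over the same cells, reordering *pred* by cell ID."""
    if isinstance(truth, Partition) and isinstance(pred, Partition):
        if set(truth.cell_ids) != set(pred.cell_ids):
            raise ValidationError("partitions cover different cell sets")
        pos = {c: i for i, c in enumerate(pred.cell_ids)}
        order = [pos[c] for c in truth.cell_ids]
        return truth.labels, pred.labels[order]
    a = truth.labels if isinstance(truth, Partition) else np.asarray(list(truth))
    b = pred.labels if isinstance(pred, Partition) else np.asarray(list(pred))
    if a.size != b.size or a.size == 0:
        raise ValidationError("label vectors must be nonempty and equal-length")
    return a, b


def ari(truth, pred) -> float:
    """Adjusted Rand index between two partitions of the same cells."""
    a, b = _aligned_labels(truth, pred)
    return float(adjusted_rand_score(a, b))


def nmi(truth, pred) -> float:
    """NMI with arithmetic-mean normalization; both-trivial convention = 1."""
    a, b = _aligned_labels(truth, pred)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def purity(truth, pred) -> float:
    """Fraction of cells in the majority true class of their cluster."""
    a, b = _aligned_labels(truth, pred)
    cm = contingency_matrix(a, b)
    return float(cm.max(axis=0).sum() / cm.sum())


def score(truth, pred) -> dict[str, float]:
    """All three indices at once."""
    return {"ari": ari(truth, pred), "nmi": nmi(truth, pred), "purity": purity(truth, pred)}
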