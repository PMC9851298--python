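"""Feature selection on edge (or gene) matrices.

Downstream clustering uses the top-k rows by sample variance across cells
(k = 500 by default). The coefficient of variation (CV = sd / |mean|) is
provided to compare the dispersion of edge features against gene features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

#: Rows whose mean magnitude falls below this are flagged as degenerate for
#: CV purposes (the ratio sd/|mean| blows up without conveying dispersion).
MEAN_EPS = 1e-12

DEFAULT_K = 500


@dataclass
class FeatureSelection:
    """Ranked selection of rows by a dispersion criterion."""

    feature_ids: list
    scores: np.ndarray
    k: int
    criterion: str

    def __len__(self) -> int:
        return len(self.feature_ids)


def _as_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValidationError("expected a nonempty 2-D matrix")
    return matrix


def top_variance_features(
    matrix: np.ndarray,
    k: int = DEFAULT_K,
    feature_ids: Sequence | None = None,
) -> FeatureSelection:
    """Select the ``min(k, n_rows)`` rows with the largest sample variance.

    Ties are broken by original row order, so the selection is
    deterministic and invariant to global rescaling of the matrix.
    """
    matrix = _as_matrix(matrix)
    if k < 1:
        raise ValidationError("k must be >= 1")
    ids = list(feature_ids) if feature_ids is not None else list(range(matrix.shape[0]))
    if len(ids) != matrix.shape[0]:
        raise ValidationError("feature_ids length does not match row count")
    var = matrix.var(axis=1, ddof=1) if matrix.shape[1] > 1 else np.zeros(matrix.shape[0])
    order = np.argsort(-var, kind="stable")[: min(k, matrix.shape[0])]
    return FeatureSelection(
        feature_ids=[ids[i] for i in order],
        scores=var[order],
        k=k,
        criterion="variance",
    )


def coefficient_of_variation(matrix: np.ndarray) -> np.ndarray:
    """Per-row CV = sample sd / |mean| across cells.

    Rows whose mean magnitude is below :data:`MEAN_EPS` get ``+inf`` as a
    sentinel; ranking helpers exclude them. Needs at least two columns.
    """
    matrix = _as_matrix(matrix)
    if matrix.shape[1] < 2:
        raise DegenerateInputError("CV needs at least 2 cells")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    cv = np.full(matrix.shape[0], np.inf)
    ok = np.abs(mean) >= MEAN_EPS
    cv[ok] = sd[ok] / np.abs(mean[ok])
    return cv


def top_cv_features(
    matrix: np.ndarray,
    k: int = DEFAULT_K,
    feature_ids: Sequence | None = None,
) -> FeatureSelection:
    """Top-k rows by CV, excluding degenerate (near-zero-mean) rows."""
    matrix = _as_matrix(matrix)
    ids = list(feature_ids) if feature_ids is not None else list(range(matrix.shape[0]))
    cv = coefficient_of_variation(matrix)
    eligible = np.flatnonzero(np.isfinite(cv))
    order = eligible[np.argsort(-cv[eligible], kind="stable")][: min(k, eligible.size)]
    return FeatureSelection(
        feature_ids=[ids[i] for i in order],
        scores=cv[order],
        k=k,
        criterion="cv",
    )
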