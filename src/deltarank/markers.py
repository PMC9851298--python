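"""Cell-type marker edges.

Marker edges are found one-vs-rest per cell type on the delta rank matrix,
mirroring how marker genes are found on an expression matrix: a two-sided
unequal-variance (Welch) t-test per edge, Benjamini-Hochberg FDR control
within each type's family of tests, and ranking of significant edges by
the fold-difference statistic

    FD(e, t) = | mean delta(e) in type t  -  mean delta(e) outside t |.

The top-k edges per type are combined, with an edge significant for more
than one type counted once in the combined set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DeltaRankMatrix
from .errors import InsufficientCellsError, ValidationError
from .network import edge_label

DEFAULT_Q_THRESHOLD = 0.01


def _group_masks(labels: np.ndarray, t) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    in_mask = labels == t
    out_mask = ~in_mask
    if in_mask.sum() < 2 or out_mask.sum() < 2:
        raise InsufficientCellsError(
            f"type {t!r}: need >= 2 cells in the type and >= 2 outside "
            f"(got {int(in_mask.sum())} / {int(out_mask.sum())})"
        )
    return in_mask, out_mask


def marker_edge_test(
    values: np.ndarray, labels: np.ndarray, t
) -> tuple[np.ndarray, np.ndarray]:
    """Welch's t-test per edge, cells of type *t* vs all other cells.

    Returns ``(t_statistics, p_values)`` aligned with the edge rows. Edges
    where both groups have zero variance get ``t = 0, p = 1`` — with no
    within-group spread the Welch statistic is undefined and such an edge
    carries no testable evidence.
    """
    values = np.asarray(values, dtype=float)
    in_mask, out_mask = _group_masks(labels, t)
    a, b = values[:, in_mask], values[:, out_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = stats.ttest_ind(a, b, axis=1, equal_var=False)
    both_flat = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    tstat = np.where(both_flat, 0.0, tstat)
    pval = np.where(both_flat, 1.0, pval)
    return np.asarray(tstat, dtype=float), np.asarray(pval, dtype=float)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("expected a nonempty 1-D array of p-values")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_fd(values: np.ndarray, labels: np.ndarray, t) -> np.ndarray:
    """FD(e, t) = |mean delta in type t - mean delta outside t| per edge."""
    values = np.asarray(values, dtype=float)
    in_mask, out_mask = _group_masks(labels, t)
    return np.abs(
        values[:, in_mask].mean(axis=1) - values[:, out_mask].mean(axis=1)
    )


@dataclass
class MarkerEdgeTable:
    """Per-type marker rows plus the deduplicated combined edge set."""

    table: pd.DataFrame
    combined_edge_ids: list[str]
    k_per_type: int
    q_threshold: float

    @property
    def n_combined(self) -> int:
        return len(self.combined_edge_ids)


def select_marker_edges(
    drm: DeltaRankMatrix,
    labels,
    k_per_type: int,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    layer: str = "normalized",
) -> MarkerEdgeTable:
    """Top-k FDR-significant, FD-ranked marker edges for every cell type.

    Per type: test every edge one-vs-rest, BH-adjust within the type,
    keep edges with q < *q_threshold*, order by FD descending (ties by
    edge order) and take the first *k_per_type*. Rows for all types are
    concatenated; the combined edge set is the union with duplicates
    collapsed. A type with no significant edge produces a warning, not an
    error.
    """
    if k_per_type < 1:
        raise ValidationError("k_per_type must be >= 1")
    values = drm.layer(layer)
    labels = np.asarray(list(labels))
    if labels.size != drm.n_cells:
        raise ValidationError(
            f"{labels.size} labels for {drm.n_cells} cells"
        )
    edge_labels = np.array([edge_label(e) for e in drm.edge_ids])
    types = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    rows: list[pd.DataFrame] = []
    combined: dict[str, None] = {}
    for t in types:
        tstat, pval = marker_edge_test(values, labels, t)
        qval = bh_fdr(pval)
        fd = fold_change_fd(values, labels, t)
        sig = np.flatnonzero(qval < q_threshold)
        if sig.size == 0:
            warnings.warn(f"cell type {t!r}: no edge passes q < {q_threshold}")
            continue
        order = sig[np.argsort(-fd[sig], kind="stable")][:k_per_type]
        rows.append(
            pd.DataFrame(
                {
                    "edge_id": edge_labels[order],
                    "cell_type": t,
                    "t_statistic": tstat[order],
                    "p_value": pval[order],
                    "q_value": qval[order],
                    "fd": fd[order],
                    "rank_within_type": np.arange(1, order.size + 1),
                }
            )
        )
        for lbl in edge_labels[order]:
            combined.setdefault(lbl)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=[
                "edge_id", "cell_type", "t_statistic", "p_value",
                "q_value", "fd", "rank_within_type",
            ]
        )
    return MarkerEdgeTable(
        table=table,
        combined_edge_ids=list(combined),
        k_per_type=k_per_type,
        q_threshold=q_threshold,
    )


def overlap_enrichment(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two ID sets.

    The probability of drawing at least ``|a & b|`` members of *set_a*
    when ``|b|`` items are sampled without replacement from a universe of
    *universe_size* items containing *set_a*.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < 1 or len(a) > universe_size or len(b) > universe_size:
        raise ValidationError(
            f"set sizes {len(a)}, {len(b)} inconsistent with universe "
            f"{universe_size}"
        )
    overlap = len(a & b)
    return float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
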