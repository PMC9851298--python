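"""Cell-specific networks from a Monte-Carlo empirical null.

A cell-specific network (CSN) is built from one cell's profile alone: each
background edge's raw delta rank is compared against an empirical null of
rank differences for random gene pairs drawn from the same cell. Under
label shuffling every edge shares one null per cell, so a single null
distribution of ``n_shuffles`` draws serves all edges of that cell. Edges
whose two-sided empirical p-value falls below ``alpha`` constitute the CSN.

For tie-free ranks the null has the closed form
``P(delta = d) = (m - |d|) / (m (m - 1))`` for ``d != 0``, which serves as
an independent oracle for the sampler.

Cell-type networks aggregate per-cell delta ranks by their mean within a
type; common-pattern summaries report, for each edge incident to a gene,
the fraction of cells whose CSN contains it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DeltaRankMatrix
from .errors import DegenerateInputError, ValidationError
from .network import BackgroundNetwork, Edge, edge_label

DEFAULT_N_SHUFFLES = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class NullDistribution:
    """Empirical null of delta ranks for one cell."""

    samples: np.ndarray
    n: int
    source_cell: str | None = None
    seed: int | None = None


@dataclass
class CellSpecificNetwork:
    """Significant edges of one cell: ``(edge, delta, p)`` triples."""

    cell_id: str
    significant_edges: list[tuple[Edge, float, float]]
    alpha: float

    @property
    def edge_set(self) -> set[Edge]:
        return {e for e, _, _ in self.significant_edges}

    def __len__(self) -> int:
        return len(self.significant_edges)


def _pair_indices(
    m: int, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform ordered pairs of distinct indices in [0, m)."""
    a = rng.integers(0, m, size=size)
    b = rng.integers(0, m - 1, size=size)
    b = np.where(b >= a, b + 1, b)
    return a, b


def empirical_null(
    rank_column: np.ndarray,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | None = None,
    source_cell: str | None = None,
) -> NullDistribution:
    """Sample the null delta-rank distribution for one cell.

    Each draw is ``r[a] - r[b]`` for an ordered pair of distinct positions
    picked uniformly from the cell's rank vector — equivalent to shuffling
    gene labels and reading a fixed edge, and valid in the presence of
    ties. Reproducible under a fixed seed.
    """
    r = np.asarray(rank_column, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise DegenerateInputError("need a rank vector with m >= 2")
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = _pair_indices(r.size, n_shuffles, rng)
    return NullDistribution(
        samples=r[a] - r[b], n=n_shuffles, source_cell=source_cell, seed=seed
    )


def analytic_null_pmf(m: int) -> dict[int, float]:
    """Closed-form null pmf for tie-free ranks of m genes.

    ``P(delta = d) = (m - |d|) / (m (m - 1))`` over the support
    ``d in {-(m-1), ..., -1, 1, ..., m-1}``; probabilities sum to 1.
    """
    if m < 2:
        raise DegenerateInputError("m must be >= 2")
    denom = m * (m - 1)
    return {
        d: (m - abs(d)) / denom
        for d in range(-(m - 1), m)
        if d != 0
    }


def empirical_pvalue(delta_obs: float, null: NullDistribution) -> float:
    """Two-sided add-one p-value: (#{|sample| >= |delta|} + 1) / (N + 1)."""
    count = int(np.count_nonzero(np.abs(null.samples) >= abs(delta_obs)))
    return (count + 1) / (null.n + 1)


def _pvalues_against(null: NullDistribution, deltas: np.ndarray) -> np.ndarray:
    sorted_abs = np.sort(np.abs(null.samples))
    # count of samples with |s| >= |d|, via the sorted complement
    ge = null.n - np.searchsorted(sorted_abs, np.abs(deltas), side="left")
    return (ge + 1) / (null.n + 1)


def cell_specific_network(
    rank_column: np.ndarray,
    net: BackgroundNetwork,
    gene_ids: list[str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    cell_id: str = "",
) -> CellSpecificNetwork:
    """Build one cell's CSN from its rank vector and the background network.

    One shared null per cell; each edge's raw delta is tested two-sided
    and retained (with its delta and p) when ``p < alpha``.
    """
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must lie in [0, 1]")
    r = np.asarray(rank_column, dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    try:
        i_idx = np.array([index[a] for a, _ in net.edges])
        j_idx = np.array([index[b] for _, b in net.edges])
    except KeyError as exc:
        raise ValidationError(
            f"network gene {exc.args[0]!r} absent from gene_ids"
        ) from None
    null = empirical_null(r, n_shuffles, seed=seed, source_cell=cell_id)
    deltas = r[i_idx] - r[j_idx]
    pvals = _pvalues_against(null, deltas)
    keep = np.flatnonzero(pvals < alpha)
    return CellSpecificNetwork(
        cell_id=cell_id,
        significant_edges=[
            (net.edges[i], float(deltas[i]), float(pvals[i])) for i in keep
        ],
        alpha=alpha,
    )


def cell_type_network(drm: DeltaRankMatrix, labels, t) -> pd.DataFrame:
    """Mean raw delta rank per edge over the cells of type *t*.

    Integrates per-cell networks into a cell-type network; edge order is
    preserved.
    """
    labels = np.asarray(list(labels))
    if labels.size != drm.n_cells:
        raise ValidationError(f"{labels.size} labels for {drm.n_cells} cells")
    mask = labels == t
    if not mask.any():
        raise ValidationError(f"unknown cell type {t!r}")
    return pd.DataFrame(
        {
            "edge_id": drm.edge_labels,
            "mean_delta": drm.raw[:, mask].mean(axis=1),
        }
    )


def common_pattern(
    csns: list[CellSpecificNetwork], net: BackgroundNetwork, gene: str
) -> pd.DataFrame:
    """Occurrence fraction of each edge incident to *gene* across CSNs.

    For every background edge touching *gene*, the fraction of input cells
    whose CSN contains that edge (in [0, 1], invariant to input order).
    """
    if not csns:
        raise ValidationError("need at least one cell-specific network")
    incident = [e for e in net.edges if gene in e]
    if not incident:
        raise ValidationError(f"gene {gene!r} is not an endpoint in the network")
    edge_sets = [c.edge_set for c in csns]
    fractions = [
        sum(e in s for s in edge_sets) / len(edge_sets) for e in incident
    ]
    return pd.DataFrame(
        {"edge_id": [edge_label(e) for e in incident], "fraction": fractions}
    )
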