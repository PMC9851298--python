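"""The delta rank matrix (DRM) transform.

Gene expression values fluctuate across measurement conditions, batches and
platforms, but the relative ordering of two genes' expression *within one
cell* is far more stable. The DRM exploits this: each cell's expression
profile is converted into within-cell ranks, and for every edge ``(g_i,
g_j)`` of an a-priori gene-interaction network the rank difference

    delta(e, c) = r_{i,c} - r_{j,c}

becomes the feature value of edge *e* in cell *c*. The resulting edges x
cells matrix is z-scored per cell (column) to give the normalized DRM.
Because ranks are invariant under any strictly increasing per-cell
transform of the expression values, so is the raw DRM — the property that
makes edge features comparable across datasets and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError, MissingGeneError, ValidationError
from .network import BackgroundNetwork, Edge, edge_label, restrict_to_genes

_TIE_METHODS = ("average", "min", "max", "dense", "ordinal")


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier {dup!r}")


@dataclass
class GeneExpressionMatrix:
    """Genes x cells matrix of nonnegative expression values (the GEM)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        m, n = self.values.shape
        if m < 2 or n < 1:
            raise ValidationError(f"need >= 2 genes and >= 1 cell, got {m} x {n}")
        if m != len(self.gene_ids) or n != len(self.cell_ids):
            raise ValidationError(
                f"shape {m} x {n} does not match {len(self.gene_ids)} gene and "
                f"{len(self.cell_ids)} cell identifiers"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class RankMatrix:
    """Within-cell ranks of all genes; columns rank independently.

    Under the default average-tie rule every column sums to
    ``m * (m + 1) / 2`` exactly.
    """

    ranks: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    tie_method: str = "average"

    def column(self, cell: str | int) -> np.ndarray:
        """One cell's rank vector, by position or cell identifier."""
        if isinstance(cell, str):
            cell = self.cell_ids.index(cell)
        return self.ranks[:, cell]


@dataclass
class DeltaRankMatrix:
    """Edges x cells matrix of delta ranks, optionally z-scored per cell.

    ``raw`` holds the plain rank differences (bounded by ``m - 1`` in
    magnitude); ``normalized`` the per-cell z-scored layer, or ``None``
    when normalization was not requested.
    """

    raw: np.ndarray
    edge_ids: list[Edge]
    cell_ids: list[str]
    normalized: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.raw.shape[0]

    @property
    def n_cells(self) -> int:
        return self.raw.shape[1]

    @property
    def edge_labels(self) -> list[str]:
        return [edge_label(e) for e in self.edge_ids]

    def layer(self, which: str = "normalized") -> np.ndarray:
        if which == "raw":
            return self.raw
        if which == "normalized":
            if self.normalized is None:
                raise ValidationError("DRM was built without the normalized layer")
            return self.normalized
        raise ValidationError(f"unknown layer {which!r}")


def rank_transform(
    gem: GeneExpressionMatrix, tie_method: str = "average"
) -> RankMatrix:
    """Rank every gene within each cell, smallest expression = rank 1.

    Ties receive the average of the ranks they span by default; all genes
    are ranked, including all-zero ones (which share the tied bottom
    ranks — two co-zero genes carry no ordering information, and average
    ties are the one rule under which their delta rank is exactly zero).
    """
    if tie_method not in _TIE_METHODS:
        raise ValidationError(f"unknown tie method {tie_method!r}")
    ranks = rankdata(gem.values, method=tie_method, axis=0)
    return RankMatrix(
        ranks=np.asarray(ranks, dtype=float),
        gene_ids=list(gem.gene_ids),
        cell_ids=list(gem.cell_ids),
        tie_method=tie_method,
    )


def delta_rank(rm: RankMatrix, net: BackgroundNetwork) -> DeltaRankMatrix:
    """Raw delta ranks: for edge ``(g_i, g_j)``, ``raw[e, c] = r_i,c - r_j,c``.

    Edge order follows the network; every endpoint must be present in the
    rank matrix (use :func:`deltarank.network.restrict_to_genes` first).
    """
    index = {g: i for i, g in enumerate(rm.gene_ids)}
    try:
        i_idx = np.array([index[a] for a, _ in net.edges])
        j_idx = np.array([index[b] for _, b in net.edges])
    except KeyError as exc:
        raise MissingGeneError(
            f"network gene {exc.args[0]!r} absent from the expression matrix"
        ) from None
    raw = rm.ranks[i_idx, :] - rm.ranks[j_idx, :]
    return DeltaRankMatrix(
        raw=raw,
        edge_ids=list(net.edges),
        cell_ids=list(rm.cell_ids),
        meta={"tie_method": rm.tie_method},
    )


def zscore_columns(raw: np.ndarray) -> np.ndarray:
    """Z-score each column (cell) over its edges.

    Uses the sample standard deviation (divisor ``l - 1``). A zero-variance
    column maps to all zeros. Requires at least two rows, otherwise the
    standard deviation is undefined.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValidationError("expected a 2-D array")
    if raw.shape[0] < 2:
        raise DegenerateInputError(
            "z-scoring needs at least 2 edges per column"
        )
    mean = raw.mean(axis=0, keepdims=True)
    sd = raw.std(axis=0, ddof=1, keepdims=True)
    out = np.zeros_like(raw)
    np.divide(raw - mean, sd, out=out, where=sd > 0)
    return out


def build_drm(
    gem: GeneExpressionMatrix,
    net: BackgroundNetwork,
    normalize: bool = True,
    tie_method: str = "average",
) -> DeltaRankMatrix:
    """Full pipeline: restrict network -> rank -> delta rank -> z-score.

    Both the raw and (when ``normalize``) z-scored layers are retained;
    ``meta`` records the dimensions before/after network restriction and
    the numerical conventions used.
    """
    restricted = restrict_to_genes(net, gem.gene_ids)
    rm = rank_transform(gem, tie_method=tie_method)
    drm = delta_rank(rm, restricted)
    if normalize:
        drm.normalized = zscore_columns(drm.raw)
    drm.meta.update(
        {
            "m": gem.n_genes,
            "n": gem.n_cells,
            "l_before": net.l,
            "l_after": restricted.l,
            "sd_ddof": 1,
            "normalized": normalize,
        }
    )
    return drm
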