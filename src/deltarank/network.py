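"""Background gene-interaction networks.

A background network is an ordered list of gene-pair edges taken from an
a-priori interaction resource (pathway databases, curated interactions).
Edges are undirected for the purpose of uniqueness, but each edge carries
the orientation in which it was first seen: the delta rank of an edge
``(g_i, g_j)`` is ``r_i - r_j``, so flipping the orientation flips the sign
of every downstream value. The first-seen orientation is therefore treated
as canonical and preserved through cleaning and restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import EmptyNetworkError, ValidationError

Edge = tuple[str, str]


@dataclass
class BackgroundNetwork:
    """Ordered, duplicate-free list of oriented gene-pair edges.

    Attributes
    ----------
    edges
        Oriented ``(gene_a, gene_b)`` pairs, no self-loops, each unordered
        pair appearing at most once.
    n_self_loops_removed, n_duplicates_removed
        Cleaning report from :func:`clean_network`.
    n_dropped
        Number of edges removed by the most recent :func:`restrict_to_genes`.
    """

    edges: list[Edge]
    n_self_loops_removed: int = 0
    n_duplicates_removed: int = 0
    n_dropped: int = 0
    _gene_set: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.edges:
            raise EmptyNetworkError("network has no edges")
        seen: set[frozenset[str]] = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"duplicate edge {{{a!r}, {b!r}}}")
            seen.add(key)
        self._gene_set = frozenset(g for e in self.edges for g in e)

    @property
    def l(self) -> int:  # noqa: E743 - the field's conventional name
        """Edge count."""
        return len(self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return self._gene_set

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)


def clean_network(raw: Sequence[Edge]) -> BackgroundNetwork:
    """Clean a raw edge list into a valid :class:`BackgroundNetwork`.

    Self-loops are dropped; duplicate unordered pairs are collapsed keeping
    the first occurrence's orientation. Counts of removed records are stored
    on the returned network.

    Raises
    ------
    ValidationError
        If *raw* is empty.
    EmptyNetworkError
        If every record was removed.
    """
    if not raw:
        raise ValidationError("raw edge list is empty")
    kept: list[Edge] = []
    seen: set[frozenset[str]] = set()
    n_loops = 0
    n_dups = 0
    for a, b in raw:
        a, b = str(a), str(b)
        if a == b:
            n_loops += 1
            continue
        key = frozenset((a, b))
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        kept.append((a, b))
    if not kept:
        raise EmptyNetworkError(
            f"all {len(raw)} records removed "
            f"({n_loops} self-loops, {n_dups} duplicates)"
        )
    return BackgroundNetwork(
        kept, n_self_loops_removed=n_loops, n_duplicates_removed=n_dups
    )


def restrict_to_genes(
    net: BackgroundNetwork, genes: Iterable[str]
) -> BackgroundNetwork:
    """Keep exactly the edges whose both endpoints are in *genes*.

    Edge order and orientation are preserved; the number of dropped edges is
    recorded on the result. Raises :class:`EmptyNetworkError` when no edge
    survives (the delta rank would be undefined for every edge).
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("gene list is empty")
    kept = [e for e in net.edges if e[0] in gene_set and e[1] in gene_set]
    if not kept:
        raise EmptyNetworkError(
            f"no edge of {net.l} has both endpoints among the {len(gene_set)} genes"
        )
    return BackgroundNetwork(
        kept,
        n_self_loops_removed=net.n_self_loops_removed,
        n_duplicates_removed=net.n_duplicates_removed,
        n_dropped=net.l - len(kept),
    )


def edge_label(edge: Edge, sep: str = "|") -> str:
    """Serialize an oriented edge as ``GENEA|GENEB``."""
    a, b = edge
    if sep in a or sep in b:
        raise ValidationError(
            f"gene identifier contains the edge separator {sep!r}: {edge!r}"
        )
    return f"{a}{sep}{b}"


def parse_edge_label(label: str, sep: str = "|") -> Edge:
    parts = label.split(sep)
    if len(parts) != 2:
        raise ValidationError(f"cannot parse edge label {label!r}")
    return (parts[0], parts[1])
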