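"""Readers and writers for the on-disk formats.

Two expression layouts are supported:

* dense table — TSV or CSV, one header row of cell IDs, first column of
  gene IDs; the delimiter is sniffed from the header line;
* Matrix-Market coordinate triplet (``.mtx``) with two sidecar files
  holding the row (gene) and column (cell/barcode) identifiers;
  CellRanger-style naming (``genes.tsv`` / ``features.tsv`` and
  ``barcodes.tsv``) is discovered automatically.

Edge lists are two-column delimited text (extra columns ignored); delta
rank matrices round-trip with edge rows serialized as ``GENEA|GENEB``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .core import DeltaRankMatrix, GeneExpressionMatrix
from .errors import FormatError, ValidationError
from .network import Edge, edge_label, parse_edge_label

_GENE_SIDECARS = ("genes.tsv", "features.tsv", "genes.txt")
_CELL_SIDECARS = ("barcodes.tsv", "cells.tsv", "barcodes.txt")
_HEADER_TOKENS = {
    "gene_a", "gene_b", "genea", "geneb", "gene1", "gene2",
    "source", "target", "from", "to", "node1", "node2",
}


def _sniff_sep(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_id_column(path: Path) -> list[str]:
    """First column of a sidecar file (extra columns tolerated)."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0].split(",")[0])
    return ids


def _find_sidecar(mtx_path: Path, candidates: tuple[str, ...]) -> Path:
    for name in candidates:
        p = mtx_path.parent / name
        if p.exists():
            return p
    raise FormatError(
        f"no sidecar file among {candidates} next to {mtx_path}"
    )


def read_expression(
    path: str | os.PathLike,
    layout: str | None = None,
    genes_path: str | os.PathLike | None = None,
    cells_path: str | os.PathLike | None = None,
) -> GeneExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``layout`` is ``"dense"`` or ``"mtx"``; when ``None`` it is inferred
    from the file suffix. Validation (nonnegative, finite, unique IDs,
    m >= 2) is enforced by :class:`GeneExpressionMatrix`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if layout is None:
        layout = "mtx" if path.suffix == ".mtx" else "dense"
    if layout == "mtx":
        gp = Path(genes_path) if genes_path else _find_sidecar(path, _GENE_SIDECARS)
        cp = Path(cells_path) if cells_path else _find_sidecar(path, _CELL_SIDECARS)
        mat = mmread(path)
        values = np.asarray(
            mat.toarray() if hasattr(mat, "toarray") else mat, dtype=float
        )
        gene_ids = _read_id_column(gp)
        cell_ids = _read_id_column(cp)
        if len(gene_ids) != values.shape[0] or len(cell_ids) != values.shape[1]:
            raise FormatError(
                f"matrix is {values.shape[0]} x {values.shape[1]} but sidecars "
                f"list {len(gene_ids)} genes and {len(cell_ids)} cells"
            )
        return GeneExpressionMatrix(values, gene_ids, cell_ids)
    if layout != "dense":
        raise ValidationError(f"unknown layout {layout!r}")
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene identifier {dup!r}")
    values = df.to_numpy(dtype=float)
    return GeneExpressionMatrix(
        values, [str(g) for g in df.index], [str(c) for c in df.columns]
    )


def write_expression(
    gem: GeneExpressionMatrix, path: str | os.PathLike, layout: str = "dense"
) -> None:
    path = Path(path)
    if layout == "dense":
        pd.DataFrame(
            gem.values, index=gem.gene_ids, columns=gem.cell_ids
        ).to_csv(path, sep="\t")
    elif layout == "mtx":
        mmwrite(str(path), csr_matrix(gem.values))
        (path.parent / "genes.tsv").write_text("\n".join(gem.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(gem.cell_ids) + "\n")
    else:
        raise ValidationError(f"unknown layout {layout!r}")


def read_network(path: str | os.PathLike) -> list[Edge]:
    """Read a raw edge list: two-column delimited text.

    An optional header row (recognized by common column names such as
    ``gene_a``/``source``) and comment lines starting with ``#`` are
    skipped; columns beyond the second are ignored. The list is returned
    in file order, uncleaned.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    pairs: list[Edge] = []
    first_data_row = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                fields = line.split("\t")
            elif "," in line:
                fields = line.split(",")
            else:
                fields = line.split()
            fields = [f.strip() for f in fields]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}:{lineno}: expected at least two columns"
                )
            if first_data_row:
                first_data_row = False
                if fields[0].lower() in _HEADER_TOKENS:
                    continue
            pairs.append((fields[0], fields[1]))
    return pairs


def write_network(net, path: str | os.PathLike, provenance: str | None = None) -> None:
    """Write a cleaned network as TSV with a provenance header comment."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(
            f"# edges={net.l} self_loops_removed={net.n_self_loops_removed} "
            f"duplicates_removed={net.n_duplicates_removed} "
            f"orientation=first-seen\n"
        )
        fh.write("gene_a\tgene_b\n")
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")


def write_delta_rank(
    drm: DeltaRankMatrix,
    path: str | os.PathLike,
    layer: str = "normalized",
    layout: str = "dense",
) -> None:
    """Write one DRM layer; edge rows are labelled ``GENEA|GENEB``.

    Serialization fails if a gene identifier contains the ``|`` delimiter.
    """
    path = Path(path)
    values = drm.layer(layer)
    labels = drm.edge_labels  # raises on delimiter collision
    if layout == "dense":
        pd.DataFrame(values, index=labels, columns=drm.cell_ids).to_csv(
            path, sep="\t"
        )
    elif layout == "mtx":
        mmwrite(str(path), csr_matrix(values))
        (path.parent / "edges.tsv").write_text("\n".join(labels) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(drm.cell_ids) + "\n")
    else:
        raise ValidationError(f"unknown layout {layout!r}")


def read_delta_rank(
    path: str | os.PathLike, layout: str = "dense"
) -> DeltaRankMatrix:
    """Read a DRM written by :func:`write_delta_rank`.

    The values land in the ``raw`` slot regardless of which layer was
    written; which layer a file holds is the caller's bookkeeping.
    """
    path = Path(path)
    if layout == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        edges = [parse_edge_label(str(lbl)) for lbl in df.index]
        cells = [str(c) for c in df.columns]
    elif layout == "mtx":
        mat = mmread(path)
        values = np.asarray(
            mat.toarray() if hasattr(mat, "toarray") else mat, dtype=float
        )
        edges = [
            parse_edge_label(lbl)
            for lbl in _read_id_column(path.parent / "edges.tsv")
        ]
        cells = _read_id_column(path.parent / "barcodes.tsv")
    else:
        raise ValidationError(f"unknown layout {layout!r}")
    return DeltaRankMatrix(raw=values, edge_ids=edges, cell_ids=cells)


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column ``cell_id <tab> type`` table into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns cell_id, type")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_labels(
    cell_ids, labels, path: str | os.PathLike, colname: str = "type"
) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), colname: list(labels)}).to_csv(
        path, sep="\t", index=False
    )
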