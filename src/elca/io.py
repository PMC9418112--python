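"""Readers and writers for hypergraph incidence data and result tables.

Three plain-text formats are supported.  Note the orientation: *files* store
one hyperedge per record (human-readable per observation), while the
in-memory :class:`~elca.data.IncidenceMatrix` is vertex-by-hyperedge;
transposition happens here at the boundary.

``tsv``
    Header ``hyperedge_id<TAB>name1<TAB>name2...``; one row per hyperedge
    with its id followed by N 0/1 cells.
``edgelist``
    Two tab-separated columns ``hyperedge_id<TAB>vertex_id``, one membership
    pair per line.
``triplet``
    Header line ``N<TAB>M``; then ``hyperedge_index<TAB>vertex_index<TAB>1``
    per membership with 1-based indices.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .data import IncidenceMatrix, from_edge_list

__all__ = [
    "read_incidence",
    "write_incidence",
    "write_labels",
    "read_labels",
    "write_bic_grid",
]

FORMATS = ("tsv", "edgelist", "triplet")


def _read_tsv(path: Path) -> IncidenceMatrix:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: header must list vertex names")
    vnames = header[1:]
    ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        ids.append(cells[0])
        row = []
        for col, c in enumerate(cells[1:], start=2):
            if c not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: non-binary cell {c!r} (column {col})")
            row.append(int(c))
        rows.append(row)
    x = np.asarray(rows, dtype=np.int8).T if rows else np.zeros((len(vnames), 0), np.int8)
    return IncidenceMatrix(x, vertex_names=vnames, hyperedge_ids=ids or None)


def _read_edgelist(path: Path, vertex_universe=None) -> IncidenceMatrix:
    pairs = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        pairs.append((cells[0], cells[1]))
    if vertex_universe is None and pairs:
        warnings.warn(
            f"{path}: no vertex universe declared; collecting vertices from pairs",
            stacklevel=2,
        )
    return from_edge_list(pairs, vertex_universe=vertex_universe)


def _read_triplet(path: Path) -> IncidenceMatrix:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n, m = (int(v) for v in lines[0].split())
    except ValueError as exc:
        raise ValueError(f"{path}:1: header must be 'N M'") from exc
    x = np.zeros((n, m), dtype=np.int8)
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split()
        if len(cells) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'edge vertex 1'")
        j, i, val = (int(v) for v in cells)
        if val != 1:
            raise ValueError(f"{path}:{lineno}: triplet value must be 1")
        if not (1 <= i <= n and 1 <= j <= m):
            raise ValueError(f"{path}:{lineno}: index out of range")
        x[i - 1, j - 1] = 1
    return IncidenceMatrix(x)


def read_incidence(path, format: str = "tsv", vertex_universe=None) -> IncidenceMatrix:
    """Read an incidence matrix; see the module docstring for formats."""
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "edgelist":
        return _read_edgelist(path, vertex_universe)
    if format == "triplet":
        return _read_triplet(path)
    raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")


def write_incidence(X: IncidenceMatrix, path, format: str = "tsv") -> None:
    """Write an incidence matrix in any of the supported formats.

    Weights are not representable in these formats; a weighted matrix is
    expanded to one record per effective hyperedge occurrence only for
    ``weights`` equal to one (otherwise an error is raised — deduplicate is
    an in-memory optimization, not a file feature).
    """
    path = Path(path)
    if not (X.weights == 1).all():
        raise ValueError("cannot serialize weighted incidence matrices")
    vnames = X.vertex_names or [f"v{i + 1}" for i in range(X.n_vertices)]
    enames = X.hyperedge_ids or [f"e{j + 1}" for j in range(X.n_hyperedges)]
    if format == "tsv":
        lines = ["\t".join(["hyperedge_id"] + vnames)]
        for j, eid in enumerate(enames):
            lines.append("\t".join([eid] + [str(int(v)) for v in X.x[:, j]]))
        path.write_text("\n".join(lines) + "\n")
    elif format == "edgelist":
        cols, rows = np.nonzero(X.x.T)  # hyperedge-major record order
        lines = [f"{enames[j]}\t{vnames[i]}" for j, i in zip(cols, rows)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "triplet":
        lines = [f"{X.n_vertices}\t{X.n_hyperedges}"]
        cols, rows = np.nonzero(X.x.T)
        lines += [f"{j + 1}\t{i + 1}\t1" for j, i in zip(cols, rows)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")


def write_labels(labels, path, hyperedge_ids=None) -> None:
    """Write simulated labels as TSV (hyperedge_id, z1, z2)."""
    path = Path(path)
    ids = hyperedge_ids or [f"e{j + 1}" for j in range(labels.z1.size)]
    lines = ["hyperedge_id\tz1\tz2"]
    lines += [f"{i}\t{a}\t{b}" for i, a, b in zip(ids, labels.z1, labels.z2)]
    path.write_text("\n".join(lines) + "\n")


def read_labels(path):
    """Read a labels TSV back into (z1, z2) integer arrays."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    z1, z2 = [], []
    for ln in lines[1:]:
        _, a, b = ln.split("\t")
        z1.append(int(a))
        z2.append(int(b))
    return np.asarray(z1), np.asarray(z2)


def write_bic_grid(grid, path) -> None:
    """Write a BIC model-selection grid as TSV (columns G, K, BIC, ...)."""
    path = Path(path)
    lines = ["G\tK\tBIC\tloglik\tconverged"]
    for G, K, b, ll, conv in grid.entries:
        lines.append(f"{G}\t{K}\t{b:.6f}\t{ll:.6f}\t{int(conv)}")
    path.write_text("\n".join(lines) + "\n")
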