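"""Incidence-matrix representation of a hypergraph.

A hypergraph on N vertices with M hyperedges is stored as the N x M binary
matrix ``x`` with ``x[i, j] = 1`` iff vertex ``i`` belongs to hyperedge ``j``
(rows = vertices, columns = hyperedges).  Hyperedges are sets of vertices and
may repeat; repeated columns can be collapsed into integer multiplicities via
:func:`deduplicate`, which leaves every weighted likelihood computation
unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "IncidenceMatrix",
    "hyperedge_sizes",
    "deduplicate",
    "from_edge_list",
    "to_edge_list",
]


@dataclass
class IncidenceMatrix:
    """N x M binary vertex-by-hyperedge incidence matrix.

    Parameters
    ----------
    x : ndarray of shape (N, M)
        Binary incidence entries; ``x[i, j] = 1`` iff vertex i is contained
        in hyperedge j.  Empty hyperedges (all-zero columns) and isolated
        vertices (all-zero rows) are legal.
    vertex_names : list of str, optional
        N unique vertex labels.
    hyperedge_ids : list of str, optional
        M unique hyperedge labels.
    weights : ndarray of int, optional
        Per-hyperedge multiplicities (>= 1); defaults to all ones.  The
        effective number of hyperedges is ``weights.sum()``.
    """

    x: np.ndarray
    vertex_names: list[str] | None = None
    hyperedge_ids: list[str] | None = None
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if self.x.ndim != 2:
            raise ValueError("incidence matrix must be 2-dimensional")
        if self.x.size and not np.isin(self.x, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        self.x = self.x.astype(np.int8, copy=False)
        n, m = self.x.shape
        if self.vertex_names is not None:
            self.vertex_names = [str(v) for v in self.vertex_names]
            if len(self.vertex_names) != n:
                raise ValueError(f"expected {n} vertex names, got {len(self.vertex_names)}")
            if len(set(self.vertex_names)) != n:
                raise ValueError("vertex names must be unique")
        if self.hyperedge_ids is not None:
            self.hyperedge_ids = [str(e) for e in self.hyperedge_ids]
            if len(self.hyperedge_ids) != m:
                raise ValueError(f"expected {m} hyperedge ids, got {len(self.hyperedge_ids)}")
            if len(set(self.hyperedge_ids)) != m:
                raise ValueError("hyperedge ids must be unique")
        if self.weights is None:
            self.weights = np.ones(m, dtype=np.int64)
        else:
            self.weights = np.asarray(self.weights)
            if self.weights.shape != (m,):
                raise ValueError("weights must have one entry per hyperedge")
            if not np.issubdtype(self.weights.dtype, np.integer):
                w = np.asarray(self.weights, dtype=float)
                if not np.all(w == np.round(w)):
                    raise ValueError("weights must be integers")
                self.weights = w.astype(np.int64)
            if (self.weights < 1).any():
                raise ValueError("weights must be >= 1")
            self.weights = self.weights.astype(np.int64)

    @property
    def n_vertices(self) -> int:
        return self.x.shape[0]

    @property
    def n_hyperedges(self) -> int:
        """Number of stored (possibly deduplicated) hyperedge columns."""
        return self.x.shape[1]

    @property
    def effective_n_hyperedges(self) -> int:
        """Total hyperedge count including multiplicities (sum of weights)."""
        return int(self.weights.sum())

    def copy(self) -> "IncidenceMatrix":
        return IncidenceMatrix(
            self.x.copy(),
            list(self.vertex_names) if self.vertex_names is not None else None,
            list(self.hyperedge_ids) if self.hyperedge_ids is not None else None,
            self.weights.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.weights, other.weights)
            and self.vertex_names == other.vertex_names
            and self.hyperedge_ids == other.hyperedge_ids
        )


def hyperedge_sizes(X: IncidenceMatrix) -> np.ndarray:
    """Cardinality of each hyperedge: ``sizes[j] = sum_i x[i, j]``."""
    return X.x.sum(axis=0).astype(np.int64)


def deduplicate(X: IncidenceMatrix) -> IncidenceMatrix:
    """Collapse identical hyperedge columns into weights.

    Returns an incidence matrix with unique columns whose weights record the
    total multiplicity of each distinct hyperedge (existing weights are
    summed).  Any weighted likelihood or E-step computation on the result
    equals the unweighted computation on the input; expanding by weights
    recovers a column permutation of the input.  Columns are kept in order of
    first appearance.  Hyperedge ids, which would no longer be one-to-one, are
    dropped when any collapse occurs.
    """
    _, first_idx, inverse = np.unique(
        X.x, axis=1, return_index=True, return_inverse=True
    )
    order = np.argsort(first_idx)  # preserve first-appearance order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    cols = first_idx[order]
    new_w = np.zeros(len(cols), dtype=np.int64)
    np.add.at(new_w, rank[inverse], X.weights)
    if len(cols) == X.n_hyperedges:
        return X.copy()
    ids = None
    return IncidenceMatrix(
        X.x[:, cols],
        list(X.vertex_names) if X.vertex_names is not None else None,
        ids,
        new_w,
    )


def from_edge_list(
    pairs: list[tuple[str, str]],
    vertex_universe: list[str] | None = None,
    hyperedge_universe: list[str] | None = None,
) -> IncidenceMatrix:
    """Build an incidence matrix from bipartite (hyperedge_id, vertex_id) pairs.

    Vertices and hyperedges are ordered by the given universes when supplied,
    otherwise by first appearance in ``pairs``.  A duplicated identical pair is
    collapsed with a warning (hyperedges are sets); a vertex outside a declared
    universe is an error.
    """
    if not pairs and vertex_universe is None:
        raise ValueError("need non-empty pairs or an explicit vertex universe")
    pairs = [(str(e), str(v)) for e, v in pairs]
    if len(set(pairs)) != len(pairs):
        warnings.warn("duplicate (hyperedge, vertex) pairs collapsed", stacklevel=2)
        seen: set[tuple[str, str]] = set()
        uniq = []
        for p in pairs:
            if p not in seen:
                seen.add(p)
                uniq.append(p)
        pairs = uniq

    if vertex_universe is not None:
        vnames = [str(v) for v in vertex_universe]
        known = set(vnames)
        for _, v in pairs:
            if v not in known:
                raise ValueError(f"vertex {v!r} not in declared universe")
    else:
        vnames = list(dict.fromkeys(v for _, v in pairs))
    if hyperedge_universe is not None:
        enames = [str(e) for e in hyperedge_universe]
        known_e = set(enames)
        for e, _ in pairs:
            if e not in known_e:
                raise ValueError(f"hyperedge {e!r} not in declared universe")
    else:
        enames = list(dict.fromkeys(e for e, _ in pairs))

    vidx = {v: i for i, v in enumerate(vnames)}
    eidx = {e: j for j, e in enumerate(enames)}
    x = np.zeros((len(vnames), len(enames)), dtype=np.int8)
    for e, v in pairs:
        x[vidx[v], eidx[e]] = 1
    return IncidenceMatrix(x, vertex_names=vnames, hyperedge_ids=enames)


def to_edge_list(X: IncidenceMatrix) -> list[tuple[str, str]]:
    """Inverse of :func:`from_edge_list`: the set of (hyperedge, vertex) pairs.

    Multiplicities (weights) are ignored: the pair set describes the distinct
    stored columns.  Default names ``v<i>`` / ``e<j>`` (1-based) are used when
    the matrix carries none.
    """
    vnames = X.vertex_names or [f"v{i + 1}" for i in range(X.n_vertices)]
    enames = X.hyperedge_ids or [f"e{j + 1}" for j in range(X.n_hyperedges)]
    cols, rows = np.nonzero(X.x.T)  # hyperedge-major pair order
    return [(enames[j], vnames[i]) for j, i in zip(cols, rows)]
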