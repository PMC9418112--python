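"""Deterministic synthetic fixtures and study parameter sets.

All fixtures are generated programmatically (no data files) and are
byte-reproducible: a given name always yields the same hypergraph.  The
parameter sets mirror the scale of typical simulation-study designs for this
model family: 10-40 vertices, 2-3 primary clusters crossed with 1-3
additional clusters, 50-1000 hyperedges, and block-structured well-separated
membership profiles.
"""

from __future__ import annotations

import numpy as np

from .data import IncidenceMatrix, from_edge_list
from .params import ELCAParams
from .simulate import SimulatedLabels, simulate

__all__ = ["make_fixture", "study_theta", "FIXTURE_NAMES"]


def study_theta(
    G: int,
    K: int,
    N: int,
    pi=None,
    tau=None,
    a=None,
    hi: float = 0.8,
    lo: float = 0.1,
) -> ELCAParams:
    """Block-structured well-separated ELCA parameters.

    Vertices are split into G contiguous blocks; phi is ``hi`` on the own
    block and ``lo`` elsewhere, so primary clusters are recoverable at
    moderate M.  Defaults: uniform pi and tau; size multipliers evenly spaced
    from 0.3 up to 1 (a single 1.0 when K = 1).
    """
    pi = np.full(G, 1.0 / G) if pi is None else np.asarray(pi, float)
    tau = np.full(K, 1.0 / K) if tau is None else np.asarray(tau, float)
    if a is None:
        a = np.linspace(0.3, 1.0, K) if K > 1 else np.array([1.0])
    phi = np.full((N, G), lo)
    bounds = np.linspace(0, N, G + 1).astype(int)
    for g in range(G):
        phi[bounds[g] : bounds[g + 1], g] = hi
    return ELCAParams(pi, tau, np.asarray(a, float), phi)


def _figure1() -> IncidenceMatrix:
    # 7-author / 4-paper coauthorship hypergraph: e1 = {v1..v4}, e2 = {v2, v3},
    # e3 = {v3, v5, v6}, e4 = {v4}
    pairs = [
        ("e1", "v1"), ("e1", "v2"), ("e1", "v3"), ("e1", "v4"),
        ("e2", "v2"), ("e2", "v3"),
        ("e3", "v3"), ("e3", "v5"), ("e3", "v6"),
        ("e4", "v4"),
    ]
    return from_edge_list(pairs, vertex_universe=[f"v{i}" for i in range(1, 8)])


_SPECS = {
    # name: (G, K, N, M, seed, overrides)
    "lca_g2": (2, 1, 20, 500, 20240101, {}),
    "elca_g2k2_sep": (2, 2, 20, 500, 20240102, {"a": [0.3, 1.0]}),
    "elca_g3k2": (3, 2, 20, 500, 20240103, {"a": [0.4, 1.0]}),
    "empty_edges": (2, 2, 6, 40, 20240104, {"a": [0.2, 1.0], "hi": 0.35, "lo": 0.02}),
}

FIXTURE_NAMES = tuple(_SPECS) + ("figure1",)


def make_fixture(
    name: str,
) -> tuple[IncidenceMatrix, ELCAParams | None, SimulatedLabels | None]:
    """Return (incidence, generating parameters, true labels) for a name.

    ``figure1`` is a fixed 7-vertex coauthorship hypergraph with no
    generating model (params and labels are None); the others are simulated
    from block-structured parameters with a fixed per-name seed.
    ``empty_edges`` is sparse enough to contain all-zero hyperedges.
    """
    if name == "figure1":
        return _figure1(), None, None
    if name not in _SPECS:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    G, K, N, M, seed, over = _SPECS[name]
    kw = dict(over)
    theta = study_theta(
        G, K, N,
        a=kw.pop("a", None),
        hi=kw.pop("hi", 0.8),
        lo=kw.pop("lo", 0.1),
        **kw,
    )
    X, labels = simulate(theta, M, seed)
    return X, theta, labels
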