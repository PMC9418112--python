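"""Parameter containers for the ELCA and LCA hyperedge-clustering models.

The extended latent class analysis (ELCA) model for a random hypergraph draws,
for each hyperedge independently, a primary cluster label g ~ Categorical(pi)
and an additional ("size") label k ~ Categorical(tau); vertex i then belongs
to the hyperedge with probability ``a_k * phi[i, g]``.  The primary profiles
``phi`` carry the membership structure while the scalars ``a`` shrink or keep
the expected hyperedge size.  Multiplying all a_k by a constant C and dividing
phi by C leaves the likelihood unchanged, so parameters are kept in the
canonical representative with ``a`` ascending and ``a[K-1] == 1``.

LCA is the K = 1 special case; conversely every ELCA(G, K) equals an LCA with
G*K classes whose profiles are proportional within groups of K — see
:func:`expand_to_lca`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ELCAParams", "LCAParams", "expand_to_lca", "n_parameters"]

_SIMPLEX_TOL = 1e-10


def _check_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError(f"{name} must be a non-empty vector")
    if (v < -_SIMPLEX_TOL).any():
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


@dataclass
class ELCAParams:
    """ELCA parameters theta = (pi, tau, a, phi) in canonical form.

    Parameters
    ----------
    pi : (G,) mixing weights of the primary clusters.
    tau : (K,) mixing weights of the additional (size) clusters.
    a : (K,) size multipliers in (0, 1]; stored ascending with ``a[-1] == 1``.
    phi : (N, G) per-vertex membership probabilities of the primary profiles.

    Construction canonicalizes: ``a`` is sorted ascending jointly with
    ``tau``, and if ``a[-1] != 1`` the scale invariance is used to rescale
    (``a -> a / a[-1]``, ``phi -> phi * a[-1]``).
    """

    pi: np.ndarray
    tau: np.ndarray
    a: np.ndarray
    phi: np.ndarray
    vertex_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.pi = _check_simplex(self.pi, "pi")
        self.tau = _check_simplex(self.tau, "tau")
        self.a = np.asarray(self.a, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.a.shape != self.tau.shape:
            raise ValueError("a and tau must have the same length K")
        if self.phi.ndim != 2 or self.phi.shape[1] != self.pi.size:
            raise ValueError("phi must be an N x G matrix")
        if (self.a <= 0).any() or (self.a > 1 + 1e-12).any():
            raise ValueError("a entries must lie in (0, 1]")
        # canonical representative: a ascending (tau permuted with it), a_K = 1
        order = np.argsort(self.a, kind="stable")
        self.a = self.a[order]
        self.tau = self.tau[order]
        aK = self.a[-1]
        if abs(aK - 1.0) > 1e-12:
            self.a = self.a / aK
            self.phi = self.phi * aK
        self.a[-1] = 1.0
        if (self.phi < -1e-12).any() or (self.phi > 1 + 1e-9).any():
            raise ValueError("phi entries must lie in [0, 1]")
        self.phi = np.clip(self.phi, 0.0, 1.0)
        if self.vertex_names is not None and len(self.vertex_names) != self.n_vertices:
            raise ValueError("vertex_names length must match phi rows")

    @property
    def G(self) -> int:
        return self.pi.size

    @property
    def K(self) -> int:
        return self.tau.size

    @property
    def n_vertices(self) -> int:
        return self.phi.shape[0]

    def permute(self, perm_primary=None, perm_additional=None) -> "ELCAParams":
        """Relabel clusters (permutations given as index arrays)."""
        pi, tau, a, phi = self.pi, self.tau, self.a, self.phi
        if perm_primary is not None:
            p = np.asarray(perm_primary)
            pi, phi = pi[p], phi[:, p]
        if perm_additional is not None:
            q = np.asarray(perm_additional)
            tau, a = tau[q], a[q]
        return ELCAParams(pi, tau, a, phi, self.vertex_names)

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "K": self.K,
            "pi": self.pi.tolist(),
            "tau": self.tau.tolist(),
            "a": self.a.tolist(),
            "phi": self.phi.tolist(),
            "vertex_names": self.vertex_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ELCAParams":
        theta = cls(
            np.array(d["pi"], dtype=float),
            np.array(d["tau"], dtype=float),
            np.array(d["a"], dtype=float),
            np.array(d["phi"], dtype=float),
            d.get("vertex_names"),
        )
        if "G" in d and theta.G != int(d["G"]):
            raise ValueError("declared G does not match pi length")
        if "K" in d and theta.K != int(d["K"]):
            raise ValueError("declared K does not match tau length")
        return theta

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_json(cls, path) -> "ELCAParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LCAParams:
    """Standard latent class analysis parameters (pi, P) for binary data.

    ``p[i, g]`` is the probability that vertex i belongs to a hyperedge of
    class g.
    """

    pi: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.pi = _check_simplex(self.pi, "pi")
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != self.pi.size:
            raise ValueError("p must be an N x G matrix")
        if (self.p < -1e-12).any() or (self.p > 1 + 1e-9).any():
            raise ValueError("p entries must lie in [0, 1]")
        self.p = np.clip(self.p, 0.0, 1.0)

    @property
    def G(self) -> int:
        return self.pi.size

    @property
    def n_vertices(self) -> int:
        return self.p.shape[0]


def expand_to_lca(theta: ELCAParams) -> LCAParams:
    """Represent an ELCA(G, K) as the equivalent LCA with G*K classes.

    Class (g, k) gets mixing weight ``pi[g] * tau[k]`` and profile
    ``a[k] * phi[:, g]``; classes are ordered with k varying fastest within g.
    The observed likelihood of any incidence matrix is identical under the
    two parameterizations.
    """
    G, K = theta.G, theta.K
    w = (theta.pi[:, None] * theta.tau[None, :]).reshape(G * K)
    p = (theta.phi[:, :, None] * theta.a[None, None, :]).reshape(
        theta.n_vertices, G * K
    )
    return LCAParams(w, p)


def n_parameters(G: int, K: int, N: int, model_kind: str = "elca") -> int:
    """Free-parameter count.

    ELCA(G, K): ``G*N + 2*(K - 1) + (G - 1)`` (profiles, the a/tau pairs, pi).
    LCA with G*K classes: ``G*K*N + (G*K - 1)``.  The two coincide at K = 1.
    """
    if G < 1 or K < 1 or N < 1:
        raise ValueError("G, K, N must be >= 1")
    if model_kind == "elca":
        return G * N + 2 * (K - 1) + (G - 1)
    if model_kind == "lca":
        return G * K * N + (G * K - 1)
    raise ValueError(f"unknown model_kind {model_kind!r}")
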