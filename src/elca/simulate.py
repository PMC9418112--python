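"""Simulation of labeled hypergraphs and exact hyperedge-size distributions.

The generative process: each hyperedge independently draws a primary label
g ~ Categorical(pi) and an additional label k ~ Categorical(tau) (the two
clusterings are a priori independent), then vertex i joins the hyperedge with
probability ``a_k * phi[i, g]``.

Conditional on (g, k) the hyperedge size is Poisson-binomial, so exact size
moments follow from the law of total variance and the exact size pmf from the
Poisson-binomial convolution per mixture component.  Two structural facts are
exposed for checking:

* an LCA matched by ``p_ig = phi_ig * sum_k a_k tau_k`` has the same mean
  hyperedge size but no larger variance than the ELCA it matches;
* when per-vertex probabilities scale like ``lambda / N`` the size
  distribution converges to a mixture of Poissons with rates
  ``lambda^(g,k) = a_k * sum_i phi_ig`` (total-variation utilities below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import IncidenceMatrix
from .params import ELCAParams, LCAParams

__all__ = [
    "SimulatedLabels",
    "SizeMoments",
    "simulate",
    "matched_lca_params",
    "exact_size_moments",
    "poisson_binomial_pmf",
    "exact_size_pmf",
    "poisson_mixture_pmf",
    "size_distribution_tv_to_poisson_limit",
]


@dataclass
class SimulatedLabels:
    """True latent labels of simulated hyperedges (1-based, lengths M)."""

    z1: np.ndarray  # primary labels in 1..G
    z2: np.ndarray  # additional labels in 1..K

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, dtype=np.int64)
        self.z2 = np.asarray(self.z2, dtype=np.int64)
        if self.z1.shape != self.z2.shape or self.z1.ndim != 1:
            raise ValueError("z1 and z2 must be equal-length vectors")


@dataclass
class SizeMoments:
    mean: float
    variance: float


def simulate(
    theta: ELCAParams, M: int, seed: int
) -> tuple[IncidenceMatrix, SimulatedLabels]:
    """Draw M hyperedges from the ELCA model.

    One generator seeds the whole call; labels are drawn first (z1 then z2),
    then the N x M incidence entries as a single uniform block compared
    against the per-cell probabilities (column-major in the hyperedge index),
    so output is bit-reproducible for a given seed.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.choice(theta.G, size=M, p=theta.pi)
    z2 = rng.choice(theta.K, size=M, p=theta.tau)
    probs = theta.phi[:, z1] * theta.a[z2][None, :]  # (N, M)
    x = (rng.uniform(size=probs.shape) < probs).astype(np.int8)
    return IncidenceMatrix(x), SimulatedLabels(z1 + 1, z2 + 1)


def matched_lca_params(theta: ELCAParams) -> LCAParams:
    """The LCA with the same primary-cluster membership probabilities.

    ``p_ig = phi_ig * sum_k a_k tau_k`` marginalizes the size clusters, so
    the matched LCA reproduces the ELCA's mean hyperedge size exactly (but
    not its extra size variance).
    """
    scale = float(np.dot(theta.a, theta.tau))
    return LCAParams(theta.pi.copy(), theta.phi * scale)


def _components(params: ELCAParams | LCAParams):
    """Mixture components as (weight, per-vertex probability vector) pairs."""
    if isinstance(params, ELCAParams):
        for g in range(params.G):
            for k in range(params.K):
                yield params.pi[g] * params.tau[k], params.a[k] * params.phi[:, g]
    else:
        for g in range(params.G):
            yield params.pi[g], params.p[:, g]


def exact_size_moments(params: ELCAParams | LCAParams) -> SizeMoments:
    """Exact mean and variance of the hyperedge size.

    Per component the size is Poisson-binomial with mean ``sum_i p_i`` and
    variance ``sum_i p_i (1 - p_i)``; the mixture moments follow from the law
    of total variance.
    """
    ws, means, cvars = [], [], []
    for w, p in _components(params):
        ws.append(w)
        means.append(p.sum())
        cvars.append(np.sum(p * (1.0 - p)))
    ws, means, cvars = map(np.asarray, (ws, means, cvars))
    mean = float(np.dot(ws, means))
    var = float(np.dot(ws, cvars) + np.dot(ws, means**2) - mean**2)
    return SizeMoments(mean=mean, variance=var)


def poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """Exact pmf (length N + 1) of a sum of independent Bernoulli(p_i).

    Dynamic-programming convolution, O(N^2); deterministic alternative to
    sampling when checking limit statements.
    """
    p = np.asarray(p, dtype=float)
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for n, pi in enumerate(p):
        pmf[1 : n + 2] = pmf[1 : n + 2] * (1.0 - pi) + pmf[: n + 1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def exact_size_pmf(params: ELCAParams | LCAParams) -> np.ndarray:
    """Exact pmf of the hyperedge size (length N + 1) under the mixture."""
    n = params.n_vertices
    pmf = np.zeros(n + 1)
    for w, p in _components(params):
        pmf += w * poisson_binomial_pmf(p)
    return pmf


def poisson_mixture_pmf(weights, rates, y) -> np.ndarray | float:
    """pmf of a finite mixture of Poisson distributions at count(s) y."""
    weights = np.asarray(weights, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if weights.shape != rates.shape:
        raise ValueError("weights and rates must align")
    if abs(weights.sum() - 1.0) > 1e-8 or (weights < 0).any():
        raise ValueError("weights must form a probability vector")
    if (rates <= 0).any():
        raise ValueError("rates must be positive")
    y_arr = np.atleast_1d(np.asarray(y))
    out = (weights[None, :] * stats.poisson.pmf(y_arr[:, None], rates[None, :])).sum(axis=1)
    return float(out[0]) if np.isscalar(y) or np.asarray(y).ndim == 0 else out


def _scaled_theta(theta: ELCAParams, n: int) -> ELCAParams:
    """Spread each primary profile's total rate evenly over n vertices."""
    lam = theta.phi.sum(axis=0)  # per-g total rate, held fixed as n grows
    phi = np.tile(lam / n, (n, 1))
    if (phi * theta.a.max() > 1).any():
        raise ValueError(f"n={n} too small for rates {lam}")
    return ELCAParams(theta.pi, theta.tau, theta.a, phi)


def size_distribution_tv_to_poisson_limit(
    theta: ELCAParams, n_vertices_sequence
) -> list[float]:
    """Total-variation distance of the exact size pmf to its Poisson limit.

    ``theta`` fixes pi, tau, a and the per-cluster total rates
    ``lambda_g = sum_i phi_ig``; for each N in the sequence the rates are
    spread evenly over N vertices (per-vertex probability lambda_g / N) and
    the exact mixed Poisson-binomial size pmf is compared against the
    limiting Poisson mixture with rates ``a_k * lambda_g`` and weights
    ``pi_g tau_k``.  Distances decrease along increasing N.
    """
    lam = theta.phi.sum(axis=0)
    rates = (lam[:, None] * theta.a[None, :]).reshape(-1)
    mix_w = (theta.pi[:, None] * theta.tau[None, :]).reshape(-1)
    out = []
    for n in n_vertices_sequence:
        scaled = _scaled_theta(theta, int(n))
        f = exact_size_pmf(scaled)
        y = np.arange(n + 1)
        if (rates > 0).all():
            h = (mix_w[None, :] * stats.poisson.pmf(y[:, None], rates[None, :])).sum(axis=1)
        else:  # degenerate components put all mass at size 0
            h = np.zeros(n + 1)
            pos = rates > 0
            if pos.any():
                h += (mix_w[None, pos] * stats.poisson.pmf(y[:, None], rates[None, pos])).sum(axis=1)
            h[0] += mix_w[~pos].sum()
        tail = max(0.0, 1.0 - h.sum())
        out.append(0.5 * (np.abs(f - h).sum() + tail))
    return out
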