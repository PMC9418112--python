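"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized code paths:
probabilities are accumulated with plain Python loops and ``math`` so that
agreement with the library is a genuine cross-check.
"""

import math

import numpy as np
import pytest

from elca import ELCAParams, IncidenceMatrix

CLAMP = 1e-12


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_theta(rng, G=None, K=None, N=None, allow_extreme=False):
    """Random valid ELCA parameters (canonical on construction)."""
    G = G or int(rng.integers(1, 4))
    K = K or int(rng.integers(1, 4))
    N = N or int(rng.integers(2, 12))
    pi = rng.dirichlet(np.ones(G))
    tau = rng.dirichlet(np.ones(K))
    lo, hi = (0.0, 1.0) if allow_extreme else (0.05, 0.95)
    phi = rng.uniform(lo, hi, size=(N, G))
    a = np.sort(rng.uniform(0.2, 1.0, size=K))
    a[-1] = 1.0
    return ELCAParams(pi, tau, a, phi)


def random_incidence(rng, N, M, density=0.4):
    return IncidenceMatrix((rng.uniform(size=(N, M)) < density).astype(int))


def brute_hyperedge_prob(x_col, theta):
    """P(hyperedge) by the plain double sum over (g, k), scalar arithmetic."""
    total = 0.0
    for g in range(theta.G):
        for k in range(theta.K):
            prod = theta.pi[g] * theta.tau[k]
            for i, xi in enumerate(x_col):
                p = theta.a[k] * theta.phi[i, g]
                p = min(max(p, CLAMP), 1 - CLAMP)
                prod *= p if xi else (1 - p)
            total += prod
    return total


def brute_responsibilities(x_col, theta):
    """E-step posterior over (g, k) for one hyperedge, scalar arithmetic."""
    num = np.zeros((theta.G, theta.K))
    for g in range(theta.G):
        for k in range(theta.K):
            prod = theta.pi[g] * theta.tau[k]
            for i, xi in enumerate(x_col):
                p = theta.a[k] * theta.phi[i, g]
                p = min(max(p, CLAMP), 1 - CLAMP)
                prod *= p if xi else (1 - p)
            num[g, k] = prod
    return num / num.sum(), num.sum()


def reference_lca_em(x, weights, pi0, p0, max_iterations, tolerance, floor):
    """Closed-form EM for the standard latent class model (K = 1 reference).

    Mirrors the package's convergence rule and parameter floor so the
    log-likelihood trace is comparable step for step: E-step by Bayes,
    M-step p_ig = weighted mean of x over responsibilities, pi = class
    frequencies.
    """
    pi, p = pi0.copy(), np.clip(p0, floor, 1 - floor)
    xt = x.T.astype(float)
    w = weights.astype(float)
    trace = []
    prev = -math.inf
    for _ in range(max_iterations):
        ll_mat = xt @ np.log(p) + (1 - xt) @ np.log1p(-p) + np.log(pi)[None, :]
        mx = ll_mat.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(ll_mat - mx).sum(axis=1))
        trace.append(float(np.dot(w, lse)))
        if prev > -math.inf and abs((trace[-1] - prev) / (abs(prev) + 1e-300)) < tolerance:
            break
        prev = trace[-1]
        z = np.exp(ll_mat - lse[:, None]) * w[:, None]
        tot = z.sum(axis=0)
        p = np.clip((x.astype(float) @ z) / tot[None, :], floor, 1 - floor)
        pi = tot / tot.sum()
    # final evaluation at the last parameters, as the package does
    ll_mat = xt @ np.log(p) + (1 - xt) @ np.log1p(-p) + np.log(pi)[None, :]
    mx = ll_mat.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(ll_mat - mx).sum(axis=1))
    ll_final = float(np.dot(w, lse))
    if abs(ll_final - trace[-1]) > 1e-12:
        trace.append(ll_final)
    return pi, p, trace
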