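"""Log-likelihood computations for ELCA / LCA hypergraph models.

All mixture sums are done in log space with log-sum-exp.  Bernoulli
probabilities are clamped to ``[1e-12, 1 - 1e-12]`` before taking logs, since
products over N vertices underflow quickly; *exact* structural zeros (an
observed vertex whose membership probability is exactly 0, or a missing vertex
whose probability is exactly 1) are restored to -inf component log-likelihoods
afterwards, so an impossible hyperedge yields a log-probability of -inf (with
a warning) rather than an exception.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import logsumexp

from .data import IncidenceMatrix
from .params import ELCAParams, LCAParams

logger = logging.getLogger(__name__)

__all__ = [
    "hyperedge_log_prob",
    "log_likelihood",
    "lca_log_likelihood",
    "complete_data_log_likelihood",
    "component_log_likelihoods",
]

_CLAMP = 1e-12


def _bernoulli_col_loglik(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-column log P(x_col | class c) for binary data.

    Parameters
    ----------
    x : (N, M) binary matrix.
    p : (N, C) per-class membership probabilities.

    Returns
    -------
    (M, C) array ``ll[j, c] = sum_i x_ij log p_ic + (1 - x_ij) log(1 - p_ic)``
    with -inf where a structural zero is violated.
    """
    xt = x.T.astype(float)
    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    ll = xt @ np.log(pc) + (1.0 - xt) @ np.log1p(-pc)
    # exact zeros / ones are genuinely impossible outcomes, not underflow
    zero = p <= 0.0
    one = p >= 1.0
    if zero.any():
        ll[(xt @ zero.astype(float)) > 0] = -np.inf
    if one.any():
        ll[((1.0 - xt) @ one.astype(float)) > 0] = -np.inf
    return ll


def component_log_likelihoods(X: IncidenceMatrix, theta: ELCAParams) -> np.ndarray:
    """(M, G, K) array of log P(hyperedge j | g, k) under theta."""
    n, G, K = theta.n_vertices, theta.G, theta.K
    if X.n_vertices != n:
        raise ValueError("incidence matrix and parameters disagree on N")
    p = (theta.phi[:, :, None] * theta.a[None, None, :]).reshape(n, G * K)
    return _bernoulli_col_loglik(X.x, p).reshape(X.n_hyperedges, G, K)


def hyperedge_log_prob(x_col: np.ndarray, theta: ELCAParams) -> float:
    """Log marginal probability of a single hyperedge.

    ``log sum_{g,k} pi_g tau_k prod_i (a_k phi_ig)^x_i (1 - a_k phi_ig)^(1-x_i)``
    evaluated by log-sum-exp over the G*K components.  Returns -inf (with a
    warning) when the hyperedge is impossible under every component.
    """
    x_col = np.asarray(x_col).reshape(-1, 1)
    X = IncidenceMatrix(x_col)
    ll = component_log_likelihoods(X, theta)[0]
    with np.errstate(divide="ignore"):
        logw = np.log(theta.pi)[:, None] + np.log(theta.tau)[None, :]
    out = float(logsumexp(ll + logw))
    if np.isneginf(out):
        logger.warning("hyperedge has probability zero under every component")
    return out


def log_likelihood(X: IncidenceMatrix, theta: ELCAParams) -> float:
    """Weighted observed-data log-likelihood of the hypergraph under ELCA."""
    ll = component_log_likelihoods(X, theta)
    with np.errstate(divide="ignore"):
        logw = np.log(theta.pi)[:, None] + np.log(theta.tau)[None, :]
    per_edge = logsumexp((ll + logw).reshape(X.n_hyperedges, -1), axis=1)
    return float(np.dot(X.weights, per_edge))


def lca_log_likelihood(X: IncidenceMatrix, params: LCAParams) -> float:
    """Weighted observed-data log-likelihood under a standard LCA."""
    if X.n_vertices != params.n_vertices:
        raise ValueError("incidence matrix and parameters disagree on N")
    ll = _bernoulli_col_loglik(X.x, params.p)
    with np.errstate(divide="ignore"):
        per_edge = logsumexp(ll + np.log(params.pi)[None, :], axis=1)
    return float(np.dot(X.weights, per_edge))


def complete_data_log_likelihood(
    X: IncidenceMatrix, z1: np.ndarray, z2: np.ndarray, theta: ELCAParams
) -> float:
    """Complete-data log-likelihood for hard assignments (z1, z2).

    ``z1`` (M x G) and ``z2`` (M x K) are one-hot indicator matrices of the
    primary and additional labels.  Marginalizing (log-sum-exp) this quantity
    over all assignments per hyperedge recovers the observed log-likelihood.
    """
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    M = X.n_hyperedges
    if z1.shape != (M, theta.G) or z2.shape != (M, theta.K):
        raise ValueError("indicator matrices have wrong shape")
    for z, name in ((z1, "z1"), (z2, "z2")):
        if not np.isin(z, (0, 1)).all() or not (z.sum(axis=1) == 1).all():
            raise ValueError(f"{name} rows must be one-hot indicators")
    ll = component_log_likelihoods(X, theta)
    with np.errstate(divide="ignore"):
        logw = np.log(theta.pi)[:, None] + np.log(theta.tau)[None, :]
    per_edge = np.einsum("jg,jk,jgk->j", z1.astype(float), z2.astype(float), ll + logw)
    return float(np.dot(X.weights, per_edge))
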