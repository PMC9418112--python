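"""BIC model selection over (G, K) grids and simulation-study metrics.

Covers: the BIC of a fitted ELCA, grid search with argmin selection,
label alignment (the optimal relabeling of estimated clusters against the
truth), aligned misclassification rates (mis1 for the primary clustering,
mis2 for the additional one), aligned l2 parameter errors, the
LCA-recovery criterion, and contingency tables between two clusterings.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._em import FitConfig, FitResult, fit
from .data import IncidenceMatrix
from .params import ELCAParams, n_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "bic",
    "BICGrid",
    "select_model",
    "align_labels",
    "parameter_error",
    "recovery_check",
    "contingency_table",
    "EvaluationReport",
    "evaluate_fit",
]


def bic(loglik: float, G: int, K: int, N: int, M: int) -> float:
    """Bayesian information criterion of an ELCA(G, K) fit.

    ``-2 log L + (G N + 2(K - 1) + (G - 1)) log M``; lower is better.  M is
    the effective hyperedge count (sum of weights when duplicates were
    collapsed).
    """
    if M < 2:
        raise ValueError("BIC needs at least two hyperedges")
    return -2.0 * loglik + n_parameters(G, K, N, "elca") * np.log(M)


@dataclass
class BICGrid:
    """Fits over a (G, K) grid with the BIC-minimizing cell.

    ``entries`` holds (G, K, bic, loglik, converged) tuples; ``selected`` is
    the (G, K) of the best converged cell (ties: fewer parameters, then
    smaller G).
    """

    entries: list[tuple[int, int, float, float, bool]]
    selected: tuple[int, int]
    fits: dict[tuple[int, int], FitResult] = field(default_factory=dict, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.entries, columns=["G", "K", "bic", "loglik", "converged"]
        )


def select_model(
    X: IncidenceMatrix,
    G_range,
    K_range,
    config: FitConfig | None = None,
    keep_fits: bool = False,
) -> BICGrid:
    """Fit every (G, K) in the grid and select the lowest BIC.

    Every cell shares the same seeding policy (the configured seed), so a
    rerun with identical inputs reproduces the grid exactly.  Cells whose
    best restart did not converge are flagged and excluded from the argmin
    unless every cell is flagged.
    """
    G_range = list(G_range)
    K_range = list(K_range)
    if not G_range or not K_range:
        raise ValueError("G_range and K_range must be non-empty")
    config = config or FitConfig()
    entries = []
    fits: dict[tuple[int, int], FitResult] = {}
    for G in G_range:
        for K in K_range:
            res = fit(X, G, K, config)
            entries.append((G, K, res.bic, res.loglik, res.converged))
            if keep_fits:
                fits[(G, K)] = res
            if not res.converged:
                logger.warning("cell (G=%d, K=%d) did not converge", G, K)
    candidates = [e for e in entries if e[4]] or entries
    n = X.n_vertices

    def keyfun(e):
        return (e[2], n_parameters(e[0], e[1], n, "elca"), e[0])

    best = min(candidates, key=keyfun)
    return BICGrid(entries=entries, selected=(best[0], best[1]), fits=fits)


def _confusion(hard: np.ndarray, true_labels: np.ndarray, C: int) -> np.ndarray:
    conf = np.zeros((C, C), dtype=np.int64)
    np.add.at(conf, (true_labels - 1, hard), 1)
    return conf


def align_labels(
    true_labels: np.ndarray, posterior: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal relabeling of posterior clusters against true labels.

    Hard labels are per-row argmax of the M x C posterior; the permutation
    (``perm[c]`` = true label, 1-based, assigned to estimated cluster c)
    minimizes total disagreement — exhaustively for C <= 5, by Hungarian
    assignment beyond.  Returns (permutation, misclassification rate).
    """
    true_labels = np.asarray(true_labels, dtype=np.int64)
    posterior = np.asarray(posterior, dtype=float)
    if posterior.ndim != 2 or posterior.shape[0] != true_labels.size:
        raise ValueError("posterior must be M x C aligned with the labels")
    C = posterior.shape[1]
    if true_labels.max(initial=1) > C or true_labels.min(initial=1) < 1:
        raise ValueError("labels must lie in 1..C")
    hard = posterior.argmax(axis=1)  # 0-based estimated cluster
    conf = _confusion(hard, true_labels, C)
    M = true_labels.size
    if C <= 5:
        best_perm, best_agree = None, -1
        for perm in itertools.permutations(range(C)):
            agree = sum(conf[perm[c], c] for c in range(C))
            if agree > best_agree:
                best_agree, best_perm = agree, perm
        perm = np.asarray(best_perm)
        agree = best_agree
    else:
        row, col = linear_sum_assignment(-conf)
        perm = np.empty(C, dtype=np.int64)
        perm[col] = row
        agree = conf[perm, np.arange(C)].sum()
    return perm + 1, float((M - agree) / M)


def parameter_error(
    theta_true: ELCAParams,
    theta_hat: ELCAParams,
    permutation_primary=None,
    permutation_additional=None,
    normalized: bool = False,
) -> tuple[float, float, float, float]:
    """Aligned l2 distances (phi, a, pi, tau) between true and estimated theta.

    Permutations are 1-based maps from estimated to true cluster labels (as
    produced by :func:`align_labels`); identity when omitted.  Each distance
    is the Euclidean norm of the flattened difference; with
    ``normalized=True`` it is divided by the square root of the number of
    entries.
    """
    if theta_true.G != theta_hat.G or theta_true.K != theta_hat.K:
        raise ValueError("dimension mismatch between true and estimated theta")
    G, K = theta_true.G, theta_true.K
    hat = theta_hat
    if permutation_primary is not None or permutation_additional is not None:
        # invert: position in the true ordering <- estimated cluster
        pp = np.arange(G) if permutation_primary is None else np.asarray(permutation_primary) - 1
        pa = np.arange(K) if permutation_additional is None else np.asarray(permutation_additional) - 1
        inv_p = np.empty(G, dtype=np.int64)
        inv_p[pp] = np.arange(G)
        inv_a = np.empty(K, dtype=np.int64)
        inv_a[pa] = np.arange(K)
        pi = hat.pi[inv_p]
        phi = hat.phi[:, inv_p]
        tau = hat.tau[inv_a]
        a = hat.a[inv_a]
    else:
        pi, phi, tau, a = hat.pi, hat.phi, hat.tau, hat.a

    def l2(u, v):
        d = float(np.linalg.norm(np.asarray(u) - np.asarray(v)))
        return d / np.sqrt(np.asarray(u).size) if normalized else d

    return (
        l2(theta_true.phi, phi),
        l2(theta_true.a, a),
        l2(theta_true.pi, pi),
        l2(theta_true.tau, tau),
    )


def recovery_check(theta_hat: ELCAParams, epsilon: float) -> bool:
    """Whether an ELCA fit collapses to the LCA special case.

    True when ``max(tau) > 1 - eps`` (one size cluster absorbs the mass) or
    ``min(a) > 1 - eps`` (all size multipliers near 1), i.e. the fitted model
    is effectively K = 1.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    return bool(
        theta_hat.tau.max() > 1 - epsilon or theta_hat.a.min() > 1 - epsilon
    )


def contingency_table(labels_a, labels_b) -> np.ndarray:
    """Cross-tabulation of two hard clusterings (1-based labels)."""
    a = np.asarray(labels_a, dtype=np.int64)
    b = np.asarray(labels_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size and (a.min() < 1 or b.min() < 1):
        raise ValueError("labels must be 1-based positive integers")
    table = np.zeros((a.max(initial=1), b.max(initial=1)), dtype=np.int64)
    np.add.at(table, (a - 1, b - 1), 1)
    return table


@dataclass
class EvaluationReport:
    """Aligned misclassification rates and parameter errors for one fit."""

    mis1: float
    mis2: float
    l2_phi: float
    l2_a: float
    l2_pi: float
    l2_tau: float
    permutation_primary: list[int]
    permutation_additional: list[int]

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def evaluate_fit(
    result: FitResult,
    theta_true: ELCAParams,
    z1_true: np.ndarray,
    z2_true: np.ndarray,
    normalized: bool = False,
) -> EvaluationReport:
    """Score a fit against simulation truth (labels 1-based)."""
    post1 = result.responsibilities.primary_marginal()
    post2 = result.responsibilities.additional_marginal()
    perm1, mis1 = align_labels(z1_true, post1)
    perm2, mis2 = align_labels(z2_true, post2)
    l2_phi, l2_a, l2_pi, l2_tau = parameter_error(
        theta_true, result.params, perm1, perm2, normalized=normalized
    )
    return EvaluationReport(
        mis1=mis1,
        mis2=mis2,
        l2_phi=l2_phi,
        l2_a=l2_a,
        l2_pi=l2_pi,
        l2_tau=l2_tau,
        permutation_primary=[int(v) for v in perm1],
        permutation_additional=[int(v) for v in perm2],
    )
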