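"""ECM fitting of the ELCA model, with MM inner steps.

One outer cycle is: a single E-step giving joint responsibilities
``z[j, g, k] = E(Z1_jg Z2_jk | X, theta)``, then conditional maximizations of
phi (all vertices/clusters), a (k < K), pi and tau against those
responsibilities.  The phi and a conditional problems have no closed form
because of the ``log(1 - a_k phi_ig)`` coupling, so each is solved by
minorize-maximize: a quadratic lower bound is placed on the concave
``log(1 - a phi)`` terms at the current point and the surrogate is maximized
exactly.  For phi the surrogate stationarity condition is a cubic; all real
roots are extracted (batched companion-matrix eigenvalues) and the candidate
maximizing the surrogate among {roots in range, bounds, current value} is
taken, which preserves the ascent guarantee.  For a the surrogate is a
concave quadratic-plus-log with a closed-form positive root.

Because every conditional step cannot decrease the minorized surrogate, the
expected complete-data log-likelihood cannot decrease, and hence neither can
the observed log-likelihood (the usual EM/ECM argument).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import IncidenceMatrix
from .params import ELCAParams, n_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "JointResponsibilities",
    "e_step",
    "cm_step_phi",
    "cm_step_a",
    "cm_step_pi",
    "cm_step_tau",
    "initialize",
    "fit",
]

_CLAMP = 1e-12

#: running count of elementary per-(vertex, hyperedge, g, k) Bernoulli terms
#: evaluated by e_step; used to verify the O(N G K M) complexity contract.
OP_COUNTS = {"e_step_terms": 0}


def reset_op_counts() -> None:
    OP_COUNTS["e_step_terms"] = 0


@dataclass
class JointResponsibilities:
    """M x G x K posterior probabilities of the joint (g, k) assignment."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 3:
            raise ValueError("responsibilities must be an M x G x K array")
        rows = self.z.reshape(self.z.shape[0], -1).sum(axis=1)
        if self.z.size and not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("responsibility rows must sum to 1")

    @property
    def n_hyperedges(self) -> int:
        return self.z.shape[0]

    def primary_marginal(self) -> np.ndarray:
        """M x G posterior of the primary label."""
        return self.z.sum(axis=2)

    def additional_marginal(self) -> np.ndarray:
        """M x K posterior of the additional (size) label."""
        return self.z.sum(axis=1)


@dataclass
class FitConfig:
    """Engineering settings of the ECM fit.

    ``mm_inner_iterations`` is the number of MM sweeps used for each of the
    phi and a conditional maximizations within one cycle (each sweep already
    guarantees ascent); ``tolerance`` is the relative change of the observed
    log-likelihood between outer iterations at which iteration stops.
    """

    n_restarts: int = 10
    max_iterations: int = 1000
    tolerance: float = 1e-8
    mm_inner_iterations: int = 2
    seed: int = 0
    param_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.max_iterations < 1:
            raise ValueError("n_restarts and max_iterations must be >= 1")
        if self.tolerance <= 0 or self.param_floor <= 0:
            raise ValueError("tolerance and param_floor must be positive")
        if self.mm_inner_iterations < 1:
            raise ValueError("mm_inner_iterations must be >= 1")


@dataclass
class FitResult:
    """Outcome of one ECM fit (best restart)."""

    params: ELCAParams
    loglik_trace: list[float]
    bic: float
    responsibilities: JointResponsibilities
    converged: bool
    n_iterations: int
    restart_logliks: list[float] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


# ---------------------------------------------------------------------------
# E-step


def _component_logp(x: np.ndarray, phi: np.ndarray, a: np.ndarray) -> np.ndarray:
    """(M, G, K) log P(col j | g, k) with probabilities clamped away from 0/1."""
    n = x.shape[0]
    G, K = phi.shape[1], a.shape[0]
    p = np.clip(phi[:, :, None] * a[None, None, :], _CLAMP, 1.0 - _CLAMP)
    p = p.reshape(n, G * K)
    xt = x.T.astype(float)
    ll = xt @ np.log(p) + (1.0 - xt) @ np.log1p(-p)
    return ll.reshape(x.shape[1], G, K)


def _e_step_arrays(
    x: np.ndarray,
    weights: np.ndarray,
    pi: np.ndarray,
    tau: np.ndarray,
    a: np.ndarray,
    phi: np.ndarray,
    hyperedge_ids=None,
):
    ll = _component_logp(x, phi, a)
    OP_COUNTS["e_step_terms"] += x.shape[0] * x.shape[1] * phi.shape[1] * a.shape[0]
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(pi)[None, :, None] + np.log(tau)[None, None, :]
    flat = logpost.reshape(logpost.shape[0], -1)
    norm = logsumexp(flat, axis=1)
    if np.isneginf(norm).any():
        j = int(np.flatnonzero(np.isneginf(norm))[0])
        name = hyperedge_ids[j] if hyperedge_ids else f"column {j}"
        raise ValueError(
            f"hyperedge {name} has zero probability under every (g, k) component"
        )
    z = np.exp(flat - norm[:, None]).reshape(logpost.shape)
    return z, float(np.dot(weights, norm))


def e_step(
    X: IncidenceMatrix, theta: ELCAParams
) -> tuple[JointResponsibilities, float]:
    """Joint responsibilities and the observed log-likelihood under theta.

    ``z[j, g, k]`` is the posterior probability that hyperedge j carries
    primary label g and additional label k; the summed log normalizers equal
    the observed log-likelihood.
    """
    z, ll = _e_step_arrays(
        X.x, X.weights.astype(float), theta.pi, theta.tau, theta.a, theta.phi,
        X.hyperedge_ids,
    )
    return JointResponsibilities(z), ll


# ---------------------------------------------------------------------------
# Conditional maximization: phi


def _phi_coefficients(x, zw, a, phi):
    """A1, A2, B1, B2 arrays of shape (N, G) for the phi surrogate.

    zw is the weighted responsibility array (M, G, K).  For each (i, g):
    A1 = sum_{j,k} zw x_ij ; A2 = sum_j zw[., g, K-1] (1 - x_ij);
    B1, B2 collect the linear and quadratic minorizer coefficients of the
    log(1 - a_k phi) terms over k < K.
    """
    xf = x.astype(float)
    one_m = 1.0 - xf
    ztot = zw.sum(axis=2)  # (M, G)
    A1 = xf @ ztot
    A2 = one_m @ zw[:, :, -1]
    K = zw.shape[2]
    if K == 1:
        zero = np.zeros_like(A1)
        return A1, A2, zero, zero
    S = np.einsum("im,mgk->igk", one_m, zw[:, :, : K - 1])
    ak = a[: K - 1]
    denom = 1.0 - ak[None, None, :] * phi[:, :, None]
    B1 = np.sum(S * (-ak[None, None, :] / denom), axis=2)
    B2 = np.sum(S * (-0.5 * ak**2 / (1.0 - ak) ** 2)[None, None, :], axis=2)
    return A1, A2, B1, B2


def _phi_qlower(phi, A1, A2, B1, B2, phi_t):
    """Surrogate objective A1 log(phi) + A2 log(1-phi) + B1 phi + B2 (phi-phi_t)^2."""
    phi = np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(A1 > 0, A1 * np.log(phi), 0.0)
        t2 = np.where(A2 > 0, A2 * np.log1p(-phi), 0.0)
    return t1 + t2 + B1 * phi + B2 * (phi - phi_t) ** 2


def _cubic_real_roots(c2, c1, c0):
    """Real roots of the monic cubics x^3 + c2 x^2 + c1 x + c0 (batched).

    Returns an (n, 3) array with NaN where a root is complex, computed via
    companion-matrix eigenvalues.
    """
    n = c2.shape[0]
    comp = np.zeros((n, 3, 3))
    comp[:, 1, 0] = 1.0
    comp[:, 2, 1] = 1.0
    comp[:, 0, 2] = -c0
    comp[:, 1, 2] = -c1
    comp[:, 2, 2] = -c2
    ev = np.linalg.eigvals(comp)
    real = np.where(np.abs(ev.imag) < 1e-9, ev.real, np.nan)
    return real


def _phi_update_all(x, zw, a, phi, floor):
    """One MM sweep updating every phi[i, g]; returns the new (N, G) matrix."""
    A1, A2, B1, B2 = _phi_coefficients(x, zw, a, phi)
    N, G = phi.shape
    lo, hi = floor, 1.0 - floor
    shape = A1.shape
    A1f, A2f, B1f, B2f, pt = (v.reshape(-1) for v in (A1, A2, B1, B2, phi))
    n_cells = A1f.size
    # candidates: up to 3 polynomial roots + bounds + current value
    cand = np.full((n_cells, 6), np.nan)
    cand[:, 3] = lo
    cand[:, 4] = hi
    cand[:, 5] = pt

    Cf = B1f - 2.0 * B2f * pt
    cubic = np.abs(B2f) > 1e-12
    if cubic.any():
        b2 = B2f[cubic]
        c2 = -(2.0 * b2 - Cf[cubic]) / (2.0 * b2)
        c1 = -(Cf[cubic] - A1f[cubic] - A2f[cubic]) / (2.0 * b2)
        c0 = -A1f[cubic] / (2.0 * b2)
        cand[cubic, :3] = _cubic_real_roots(c2, c1, c0)
    quad = (~cubic) & (np.abs(B1f) > 1e-12)
    if quad.any():
        # stationarity with B2 = 0: B1 phi^2 + (A1 + A2 - B1) phi - A1 = 0
        b = A1f[quad] + A2f[quad] - B1f[quad]
        disc = b**2 + 4.0 * B1f[quad] * A1f[quad]
        disc = np.where(disc >= 0, disc, np.nan)
        sq = np.sqrt(disc)
        cand[quad, 0] = (-b + sq) / (2.0 * B1f[quad])
        cand[quad, 1] = (-b - sq) / (2.0 * B1f[quad])
    closed = (~cubic) & (~quad)
    if closed.any():
        tot = A1f[closed] + A2f[closed]
        with np.errstate(invalid="ignore", divide="ignore"):
            cand[closed, 0] = np.where(tot > 0, A1f[closed] / np.maximum(tot, _CLAMP), pt[closed])

    with np.errstate(invalid="ignore"):
        inside = (cand > lo) & (cand < hi)
    cand = np.where(inside | (np.arange(6) >= 3), cand, np.nan)
    q = _phi_qlower(cand, A1f[:, None], A2f[:, None], B1f[:, None], B2f[:, None], pt[:, None])
    q = np.where(np.isnan(cand), -np.inf, q)
    best = np.argmax(q, axis=1)
    new = np.clip(cand[np.arange(n_cells), best], lo, hi)
    return new.reshape(shape)


def cm_step_phi(
    X: IncidenceMatrix,
    z: JointResponsibilities,
    theta_current: ELCAParams,
    i: int,
    g: int,
    param_floor: float = 1e-6,
) -> float:
    """Single MM update of phi[i, g] given responsibilities from theta_current.

    Builds the quadratic minorizer of the conditional objective in phi[i, g],
    solves its cubic stationarity equation and returns the candidate (real
    root in range, bound, or current value) maximizing the surrogate.
    """
    zw = z.z * X.weights.astype(float)[:, None, None]
    new = _phi_update_all(X.x, zw, theta_current.a, theta_current.phi, param_floor)
    return float(new[i, g])


# ---------------------------------------------------------------------------
# Conditional maximization: a


def _a_coefficients(x, zw, phi, a):
    """A, B, C vectors (length K) for the a surrogate (entry K-1 unused)."""
    xf = x.astype(float)
    one_m = 1.0 - xf
    SX = np.einsum("im,mgk->igk", xf, zw)
    S0 = np.einsum("im,mgk->igk", one_m, zw)
    A = SX.sum(axis=(0, 1))
    K = a.shape[0]
    denom = 1.0 - a[None, None, :] * phi[:, :, None]  # (N, G, K)
    B = np.sum(S0 * (-phi[:, :, None] / denom), axis=(0, 1))
    curv = -0.5 * (phi**2) / (1.0 - phi) ** 2
    C = np.sum(S0 * curv[:, :, None], axis=(0, 1))
    return A, B, C


def _a_qlower(a_val, A, B, C, a_t):
    """Surrogate A log(a) + B a + C (a - a_t)^2."""
    a_val = np.asarray(a_val, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(A > 0, A * np.log(a_val), 0.0)
    return t1 + B * a_val + C * (a_val - a_t) ** 2


def _a_update_all(x, zw, phi, a, floor):
    """One MM sweep over a[k], k < K; a[K-1] stays pinned at 1."""
    K = a.shape[0]
    if K == 1:
        return a.copy()
    A, B, C = _a_coefficients(x, zw, phi, a)
    new = a.copy()
    lo, hi = floor, 1.0 - floor
    for k in range(K - 1):
        if C[k] >= -1e-300:
            # no curvature mass: surrogate is A log a + B a, increasing when
            # B >= 0; take the upper clamp (logged) else the stationary -A/B
            logger.info("a-step: zero curvature for additional cluster %d", k)
            if B[k] >= 0 or A[k] <= 0:
                new[k] = hi if B[k] >= 0 else lo
            else:
                new[k] = np.clip(-A[k] / B[k], lo, hi)
            continue
        D = B[k] / (2.0 * C[k]) - a[k]
        E = -A[k] / (2.0 * C[k])
        a_hat = np.sqrt(max(E + D * D / 4.0, 0.0)) - D / 2.0
        new[k] = np.clip(a_hat, lo, hi)
    return new


def cm_step_a(
    X: IncidenceMatrix,
    z: JointResponsibilities,
    theta_current: ELCAParams,
    k: int,
    param_floor: float = 1e-6,
) -> float:
    """Single MM update of a[k] (k < K) given responsibilities.

    Closed form: with D = B/(2C) - a_t and E = -A/(2C), the surrogate maximum
    is ``sqrt(E + D^2/4) - D/2``, clamped into [floor, 1 - floor].
    """
    if k >= theta_current.K - 1:
        raise ValueError("a[K-1] is pinned at 1 and never updated")
    zw = z.z * X.weights.astype(float)[:, None, None]
    new = _a_update_all(X.x, zw, theta_current.phi, theta_current.a, param_floor)
    return float(new[k])


# ---------------------------------------------------------------------------
# Mixing weights


def cm_step_pi(z: JointResponsibilities, weights: np.ndarray | None = None) -> np.ndarray:
    """Lagrange update: pi_g proportional to the total primary responsibility."""
    w = np.ones(z.n_hyperedges) if weights is None else np.asarray(weights, float)
    tot = np.einsum("j,jgk->g", w, z.z)
    return tot / tot.sum()


def cm_step_tau(z: JointResponsibilities, weights: np.ndarray | None = None) -> np.ndarray:
    """Lagrange update: tau_k proportional to the total additional responsibility."""
    w = np.ones(z.n_hyperedges) if weights is None else np.asarray(weights, float)
    tot = np.einsum("j,jgk->k", w, z.z)
    return tot / tot.sum()


# ---------------------------------------------------------------------------
# Initialization and the outer loop


def initialize(X: IncidenceMatrix, G: int, K: int, seed: int) -> ELCAParams:
    """Random starting point: flat-Dirichlet pi/tau, phi ~ U(0.2, 0.8),
    a sorted U(0.2, 1) with the top entry pinned at 1."""
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(G))
    tau = rng.dirichlet(np.ones(K))
    phi = rng.uniform(0.2, 0.8, size=(X.n_vertices, G))
    a = np.sort(rng.uniform(0.2, 1.0, size=K))
    a[-1] = 1.0
    return ELCAParams(pi, tau, a, phi)


def _canonical_arrays(pi, tau, a, phi):
    order = np.argsort(a, kind="stable")
    return pi, tau[order], a[order], phi


def _run_single(x, weights, pi, tau, a, phi, config: FitConfig, ids=None):
    """One restart of the ECM loop on raw arrays; returns trace and state."""
    floor = config.param_floor
    phi = np.clip(phi, floor, 1.0 - floor)
    K = a.shape[0]
    trace: list[float] = []
    prev = -np.inf
    converged = False
    z = None
    for _ in range(config.max_iterations):
        z, ll = _e_step_arrays(x, weights, pi, tau, a, phi, ids)
        trace.append(ll)
        if prev > -np.inf:
            rel = (ll - prev) / (abs(prev) + 1e-300)
            if abs(rel) < config.tolerance:
                converged = True
                break
        prev = ll
        zw = z * weights[:, None, None]
        for _ in range(config.mm_inner_iterations):
            phi = _phi_update_all(x, zw, a, phi, floor)
        if K > 1:
            for _ in range(config.mm_inner_iterations):
                a = _a_update_all(x, zw, phi, a, floor)
        tot = zw.sum(axis=(0, 2))
        pi = tot / tot.sum()
        tot_k = zw.sum(axis=(0, 1))
        tau = tot_k / tot_k.sum()
        pi, tau, a, phi = _canonical_arrays(pi, tau, a, phi)
    return pi, tau, a, phi, trace, converged


def fit(
    X: IncidenceMatrix,
    G: int,
    K: int,
    config: FitConfig | None = None,
    init: ELCAParams | None = None,
) -> FitResult:
    """Fit the ELCA(G, K) model by restarted ECM; returns the best restart.

    Restart r uses a deterministic seed derived from ``config.seed``; the
    first restart uses ``init`` when given.  The winner is the restart with
    the highest final observed log-likelihood (ties below 1e-9 go to the
    lower restart index), re-canonicalized so that a is ascending with
    ``a[K-1] = 1``.
    """
    config = config or FitConfig()
    if G < 1 or K < 1:
        raise ValueError("G and K must be >= 1")
    if X.n_hyperedges < 1:
        raise ValueError("need at least one hyperedge")
    if X.x.sum() == 0:
        logger.warning("all-zero incidence matrix: phi will sit at the floor")
    if G * K > X.effective_n_hyperedges:
        logger.warning("G*K exceeds the number of hyperedges; BIC unreliable")

    weights = X.weights.astype(float)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_restarts)
    seeds = (seeds % (2**31 - 1)).astype(np.int64)

    best = None
    restart_logliks: list[float] = []
    for r in range(config.n_restarts):
        if r == 0 and init is not None:
            theta0 = init
        else:
            theta0 = initialize(X, G, K, int(seeds[r]))
        out = _run_single(
            X.x, weights, theta0.pi, theta0.tau, theta0.a, theta0.phi, config,
            X.hyperedge_ids,
        )
        ll = out[4][-1]
        restart_logliks.append(ll)
        if best is None or ll > best[4][-1] + 1e-9:
            best = out

    pi, tau, a, phi, trace, converged = best
    theta = ELCAParams(pi, tau, a, phi, vertex_names=X.vertex_names)
    z, ll_final = _e_step_arrays(
        X.x, weights, theta.pi, theta.tau, theta.a, theta.phi, X.hyperedge_ids
    )
    trace = list(trace)
    if abs(ll_final - trace[-1]) > 1e-12:
        trace.append(ll_final)
    m_eff = X.effective_n_hyperedges
    bic_val = -2.0 * ll_final + n_parameters(G, K, X.n_vertices, "elca") * np.log(m_eff)
    return FitResult(
        params=theta,
        loglik_trace=trace,
        bic=float(bic_val),
        responsibilities=JointResponsibilities(z),
        converged=converged,
        n_iterations=len(trace),
        restart_logliks=restart_logliks,
    )
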