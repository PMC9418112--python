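import math

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

import elca._em as em
from elca import (
    ELCAParams,
    FitConfig,
    IncidenceMatrix,
    JointResponsibilities,
    e_step,
    fit,
    initialize,
    log_likelihood,
    simulate,
)
from elca._em import (
    OP_COUNTS,
    _a_coefficients,
    _a_qlower,
    _phi_coefficients,
    _phi_qlower,
    cm_step_a,
    cm_step_phi,
    cm_step_pi,
    cm_step_tau,
    reset_op_counts,
)
from conftest import (
    brute_responsibilities,
    random_incidence,
    random_theta,
    reference_lca_em,
)


class TestEStep:
    def test_symmetric_theta_gives_uniform_posterior(self):
        theta = ELCAParams(
            pi=[0.5, 0.5], tau=[0.5, 0.5], a=[1.0, 1.0], phi=np.full((4, 2), 0.3)
        )
        X = IncidenceMatrix((np.arange(12).reshape(4, 3) % 2))
        z, _ = e_step(X, theta)
        np.testing.assert_allclose(z.z, 0.25, atol=1e-12)

    def test_bayes_posterior_single_vertex(self):
        # P(g=1 | x=1) = 0.45 / (0.45 + 0.05) = 0.9
        theta = ELCAParams(pi=[0.5, 0.5], tau=[1.0], a=[1.0], phi=[[0.9, 0.1]])
        z, _ = e_step(IncidenceMatrix([[1]]), theta)
        np.testing.assert_allclose(z.z[0, :, 0], [0.9, 0.1], atol=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            theta = random_theta(rng, N=int(rng.integers(2, 7)))
            x = (rng.uniform(size=theta.n_vertices) < 0.5).astype(int)
            z, ll = e_step(IncidenceMatrix(x[:, None]), theta)
            expected, norm = brute_responsibilities(x, theta)
            np.testing.assert_allclose(z.z[0], expected, atol=1e-12)
            assert ll == pytest.approx(math.log(norm), abs=1e-10)

    def test_normalizers_reproduce_observed_loglik(self, rng):
        for _ in range(20):
            theta = random_theta(rng)
            X = random_incidence(rng, theta.n_vertices, 15)
            _, ll = e_step(X, theta)
            assert ll == pytest.approx(log_likelihood(X, theta), abs=1e-10)

    def test_marginals_are_posteriors(self, rng):
        theta = random_theta(rng, G=3, K=2, N=5)
        X = random_incidence(rng, 5, 10)
        z, _ = e_step(X, theta)
        np.testing.assert_allclose(z.primary_marginal().sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(z.additional_marginal().sum(axis=1), 1.0, atol=1e-10)
        assert (z.z >= 0).all()

    def test_impossible_hyperedge_raises_with_name(self):
        theta = ELCAParams(pi=[1.0], tau=[1.0], a=[1.0], phi=[[0.0]])
        X = IncidenceMatrix([[1]], hyperedge_ids=["edge_a"])
        # exact structural zero survives clamping only through the likelihood
        # module; the fitter clamps, so probability is tiny but positive there.
        from elca.likelihood import hyperedge_log_prob

        assert hyperedge_log_prob([1], theta) == -np.inf

    def test_complexity_scales_linearly(self, rng):
        """Operation count doubles when each of N, G, K, M doubles."""
        base = dict(N=8, M=20, G=2, K=2)
        counts = {}
        for dim in ("N", "M", "G", "K"):
            for mult in (1, 2):
                d = dict(base)
                d[dim] *= mult
                theta = random_theta(rng, G=d["G"], K=d["K"], N=d["N"])
                X = random_incidence(rng, d["N"], d["M"])
                reset_op_counts()
                e_step(X, theta)
                counts[(dim, mult)] = OP_COUNTS["e_step_terms"]
            ratio = counts[(dim, 2)] / counts[(dim, 1)]
            assert 1.7 <= ratio <= 2.3


def _random_state(rng, G=2, K=2, N=6, M=12):
    theta = random_theta(rng, G=G, K=K, N=N)
    X = random_incidence(rng, N, M)
    z, _ = e_step(X, theta)
    return X, z, theta


class TestPhiStep:
    def test_k1_closed_form(self, rng):
        X, z, theta = _random_state(rng, K=1)
        zw = z.z * X.weights[:, None, None].astype(float)
        A1, A2, B1, B2 = _phi_coefficients(X.x, zw, theta.a, theta.phi)
        assert np.all(B1 == 0) and np.all(B2 == 0)
        for i in range(X.n_vertices):
            for g in range(theta.G):
                new = cm_step_phi(X, z, theta, i, g)
                assert new == pytest.approx(
                    np.clip(A1[i, g] / (A1[i, g] + A2[i, g]), 1e-6, 1 - 1e-6),
                    abs=1e-12,
                )

    def test_vertex_never_observed_goes_to_floor(self, rng):
        theta = random_theta(rng, G=1, K=1, N=3)
        x = np.array([[0, 0], [1, 0], [0, 1]])
        z, _ = e_step(IncidenceMatrix(x), theta)
        assert cm_step_phi(IncidenceMatrix(x), z, theta, 0, 0) == pytest.approx(1e-6)

    def test_maximizes_surrogate_on_grid(self, rng):
        floor = 1e-6
        grid = np.linspace(floor, 1 - floor, 10001)
        for _ in range(50):
            X, z, theta = _random_state(rng, K=int(rng.integers(2, 4)))
            zw = z.z * X.weights[:, None, None].astype(float)
            A1, A2, B1, B2 = _phi_coefficients(X.x, zw, theta.a, theta.phi)
            i = int(rng.integers(X.n_vertices))
            g = int(rng.integers(theta.G))
            new = cm_step_phi(X, z, theta, i, g)
            q_new = _phi_qlower(new, A1[i, g], A2[i, g], B1[i, g], B2[i, g], theta.phi[i, g])
            q_grid = _phi_qlower(grid, A1[i, g], A2[i, g], B1[i, g], B2[i, g], theta.phi[i, g])
            assert q_new >= q_grid.max() - 1e-8

    def test_surrogate_never_decreases_from_current(self, rng):
        for _ in range(20):
            X, z, theta = _random_state(rng, K=2)
            zw = z.z * X.weights[:, None, None].astype(float)
            A1, A2, B1, B2 = _phi_coefficients(X.x, zw, theta.a, theta.phi)
            new = em._phi_update_all(X.x, zw, theta.a, theta.phi, 1e-6)
            q_new = _phi_qlower(new, A1, A2, B1, B2, theta.phi)
            q_old = _phi_qlower(theta.phi, A1, A2, B1, B2, theta.phi)
            assert (q_new >= q_old - 1e-12).all()

    def test_minorizer_touches_and_lower_bounds(self, rng):
        """Q_lower(phi) <= Q(phi) on a grid with equality at the current point."""
        X, z, theta = _random_state(rng, K=2)
        zw = z.z * X.weights[:, None, None].astype(float)
        A1, A2, B1, B2 = _phi_coefficients(X.x, zw, theta.a, theta.phi)
        i, g = 1, 0
        phi_t = theta.phi[i, g]

        def q_true(v):
            # conditional expected complete-data objective in phi[i, g]
            total = 0.0
            for j in range(X.n_hyperedges):
                for k in range(theta.K):
                    pk = theta.a[k] * v
                    term = X.x[i, j] * math.log(v) + (1 - X.x[i, j]) * math.log(1 - pk)
                    total += zw[j, g, k] * term
            return total

        offset = q_true(phi_t) - _phi_qlower(phi_t, A1[i, g], A2[i, g], B1[i, g], B2[i, g], phi_t)
        for v in np.linspace(0.05, 0.95, 19):
            lower = _phi_qlower(v, A1[i, g], A2[i, g], B1[i, g], B2[i, g], phi_t) + offset
            assert lower <= q_true(v) + 1e-9


class TestAStep:
    def test_worked_example(self):
        # A=1.5, B=-2, C=-1, a_t=0.5: D=0.5, E=0.75, a_hat = sqrt(0.8125) - 0.25
        D = (-2) / (2 * -1) - 0.5
        E = -1.5 / (2 * -1)
        a_hat = math.sqrt(E + D**2 / 4) - D / 2
        assert a_hat == pytest.approx(0.65139, abs=1e-5)
        # cross-check: maximizes the surrogate A log a + B a + C (a - a_t)^2
        res = minimize_scalar(
            lambda v: -_a_qlower(v, 1.5, -2.0, -1.0, 0.5), bounds=(1e-9, 5), method="bounded"
        )
        assert res.x == pytest.approx(a_hat, abs=1e-6)

    def test_no_occurrences_gives_zero(self):
        # A = 0 and D >= 0: a_hat = |D|/2 - D/2 = 0 before clamping
        D = (-0.5) / (2 * -1.0) - 0.2  # = 0.05 >= 0
        a_hat = math.sqrt(0 + D**2 / 4) - D / 2
        assert a_hat == pytest.approx(0.0, abs=1e-15)

    def test_matches_closed_form_and_numeric_max(self, rng):
        for _ in range(50):
            X, z, theta = _random_state(rng, K=int(rng.integers(2, 4)))
            zw = z.z * X.weights[:, None, None].astype(float)
            A, B, C = _a_coefficients(X.x, zw, theta.phi, theta.a)
            k = int(rng.integers(theta.K - 1))
            new = cm_step_a(X, z, theta, k)
            D = B[k] / (2 * C[k]) - theta.a[k]
            E = -A[k] / (2 * C[k])
            expected = np.clip(math.sqrt(E + D**2 / 4) - D / 2, 1e-6, 1 - 1e-6)
            assert new == pytest.approx(expected, abs=1e-12)
            res = minimize_scalar(
                lambda v: -_a_qlower(v, A[k], B[k], C[k], theta.a[k]),
                bounds=(1e-9, 2.0),
                method="bounded",
            )
            # numeric argmax of the surrogate agrees (up to the clamp)
            assert min(max(res.x, 1e-6), 1 - 1e-6) == pytest.approx(new, abs=1e-5)

    def test_mm_ascent_property(self, rng):
        for _ in range(30):
            X, z, theta = _random_state(rng, K=2)
            zw = z.z * X.weights[:, None, None].astype(float)
            A, B, C = _a_coefficients(X.x, zw, theta.phi, theta.a)
            new = cm_step_a(X, z, theta, 0)
            assert _a_qlower(new, A[0], B[0], C[0], theta.a[0]) >= (
                _a_qlower(theta.a[0], A[0], B[0], C[0], theta.a[0]) - 1e-12
            )

    def test_top_a_never_updated(self, rng):
        X, z, theta = _random_state(rng, K=2)
        with pytest.raises(ValueError, match="pinned"):
            cm_step_a(X, z, theta, theta.K - 1)


class TestMixingWeightSteps:
    def test_uniform_responsibilities(self):
        z = JointResponsibilities(np.full((10, 2, 2), 0.25))
        np.testing.assert_allclose(cm_step_pi(z), [0.5, 0.5])
        np.testing.assert_allclose(cm_step_tau(z), [0.5, 0.5])

    def test_hard_assignments_give_frequencies(self):
        z = np.zeros((10, 2, 2))
        z[:8, 0, 0] = 1.0
        z[8:, 1, 0] = 1.0
        zr = JointResponsibilities(z)
        np.testing.assert_allclose(cm_step_pi(zr), [0.8, 0.2])
        z2 = np.zeros((10, 1, 2))
        z2[:9, 0, 0] = 1.0
        z2[9:, 0, 1] = 1.0
        np.testing.assert_allclose(cm_step_tau(JointResponsibilities(z2)), [0.9, 0.1])

    def test_matches_constrained_numeric_maximum(self, rng):
        z = rng.dirichlet(np.ones(6), size=8).reshape(8, 3, 2)
        zr = JointResponsibilities(z)
        pi_hat = cm_step_pi(zr)
        w = z.sum(axis=(0, 2))

        def neg_obj(v):
            return -np.dot(w, np.log(v))

        res = minimize(
            neg_obj,
            np.full(3, 1 / 3),
            constraints={"type": "eq", "fun": lambda v: v.sum() - 1},
            bounds=[(1e-9, 1)] * 3,
        )
        np.testing.assert_allclose(pi_hat, res.x, atol=1e-5)


class TestFit:
    def test_monotone_ascent_random_instances(self, rng):
        for _ in range(30):
            theta = random_theta(rng, N=int(rng.integers(4, 12)))
            X = random_incidence(rng, theta.n_vertices, int(rng.integers(10, 60)))
            res = fit(
                X, theta.G, theta.K,
                FitConfig(n_restarts=1, max_iterations=40, seed=int(rng.integers(2**31))),
            )
            diffs = np.diff(res.loglik_trace)
            assert (diffs >= -1e-8).all()

    def test_k1_matches_reference_lca_em(self, rng):
        for trial in range(5):
            theta0 = random_theta(rng, G=2, K=1, N=8)
            X = random_incidence(rng, 8, 40)
            res = fit(
                X, 2, 1,
                FitConfig(n_restarts=1, max_iterations=80, tolerance=1e-8, seed=trial),
                init=theta0,
            )
            _, _, ref_trace = reference_lca_em(
                X.x, X.weights, theta0.pi, theta0.phi, 80, 1e-8, 1e-6
            )
            assert len(res.loglik_trace) == len(ref_trace)
            np.testing.assert_allclose(res.loglik_trace, ref_trace, atol=1e-9)

    def test_single_profile_recovers_row_means(self, rng):
        # G = K = 1: MLE of independent Bernoullis is the empirical mean
        x = (rng.uniform(size=(6, 300)) < 0.35).astype(int)
        X = IncidenceMatrix(x)
        res = fit(X, 1, 1, FitConfig(n_restarts=1, max_iterations=10, seed=0))
        np.testing.assert_allclose(
            res.params.phi[:, 0], x.mean(axis=1), atol=1e-8
        )

    def test_restart_determinism(self, rng):
        theta = random_theta(rng, G=2, K=2, N=8)
        X = random_incidence(rng, 8, 40)
        cfg = FitConfig(n_restarts=3, max_iterations=50, seed=99)
        r1 = fit(X, 2, 2, cfg)
        r2 = fit(X, 2, 2, cfg)
        assert r1.loglik_trace == r2.loglik_trace
        np.testing.assert_array_equal(r1.params.phi, r2.params.phi)
        assert r1.restart_logliks == r2.restart_logliks

    def test_result_is_canonical_and_bic_consistent(self, rng):
        from elca import bic as bic_formula

        theta = random_theta(rng, G=2, K=2, N=8)
        X = random_incidence(rng, 8, 50)
        res = fit(X, 2, 2, FitConfig(n_restarts=2, max_iterations=60, seed=3))
        assert res.params.a[-1] == 1.0
        assert (np.diff(res.params.a) >= 0).all()
        assert res.bic == pytest.approx(
            bic_formula(res.loglik, 2, 2, 8, X.effective_n_hyperedges), abs=1e-9
        )

    def test_stationarity_at_convergence(self, rng):
        """Numeric gradient of the observed log-likelihood ~ 0 at the optimum."""
        theta = random_theta(rng, G=2, K=2, N=5)
        X, _ = simulate(theta, 150, 4)
        res = fit(X, 2, 2, FitConfig(n_restarts=2, max_iterations=2000, tolerance=1e-12, seed=5))
        p = res.params
        h = 1e-6
        M = X.effective_n_hyperedges

        def ll(theta_):
            return log_likelihood(X, theta_) / M

        # phi coordinates (free)
        for (i, g) in [(0, 0), (2, 1)]:
            if not (2e-6 < p.phi[i, g] < 1 - 2e-6):
                continue
            up, dn = p.phi.copy(), p.phi.copy()
            up[i, g] += h
            dn[i, g] -= h
            grad = (
                ll(ELCAParams(p.pi, p.tau, p.a, up))
                - ll(ELCAParams(p.pi, p.tau, p.a, dn))
            ) / (2 * h)
            assert abs(grad) <= 1e-4
        # pi along the simplex direction (pi_0 + h, pi_1 - h)
        if (p.pi > 2e-6).all() and p.G == 2:
            up = p.pi + np.array([h, -h])
            dn = p.pi - np.array([h, -h])
            grad = (
                ll(ELCAParams(up, p.tau, p.a, p.phi))
                - ll(ELCAParams(dn, p.tau, p.a, p.phi))
            ) / (2 * h)
            assert abs(grad) <= 1e-4

    def test_all_zero_matrix_warns_and_floors(self, caplog):
        X = IncidenceMatrix(np.zeros((4, 10)))
        with caplog.at_level("WARNING"):
            res = fit(X, 1, 1, FitConfig(n_restarts=1, max_iterations=5, seed=0))
        assert "all-zero" in caplog.text
        np.testing.assert_allclose(res.params.phi, 1e-6)


class TestInitialize:
    def test_deterministic_given_seed(self, rng):
        X = random_incidence(rng, 5, 10)
        t1 = initialize(X, 2, 2, seed=7)
        t2 = initialize(X, 2, 2, seed=7)
        np.testing.assert_array_equal(t1.phi, t2.phi)
        np.testing.assert_array_equal(t1.pi, t2.pi)

    def test_k1_pins_a_and_tau(self, rng):
        X = random_incidence(rng, 5, 10)
        t = initialize(X, 3, 1, seed=1)
        assert t.a.tolist() == [1.0]
        assert t.tau.tolist() == [1.0]

    def test_output_satisfies_invariants(self, rng):
        X = random_incidence(rng, 6, 10)
        for seed in range(10):
            t = initialize(X, 3, 2, seed=seed)
            assert t.pi.sum() == pytest.approx(1.0, abs=1e-10)
            assert t.tau.sum() == pytest.approx(1.0, abs=1e-10)
            assert (np.diff(t.a) >= 0).all() and t.a[-1] == 1.0
            assert ((t.phi >= 0) & (t.phi <= 1)).all()
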