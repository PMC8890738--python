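import numpy as np
import pytest

from cochreg.metrics import MetricEvaluation
from cochreg.optimizers import (LBFGSMemory, OptimizerConfig, OptimizerState,
                                StochasticObjective, asgd_run, compute_delta,
                                estimate_noise_factor, estimate_preconditioner,
                                fasgd_run, fpsgd_run, gd_step, lbfgs_two_loop,
                                slbfgs_run, step_size_sequence)
from cochreg.rigid_transform import RigidTransform, transform_points
from cochreg.volume_model import Image3D

from conftest import make_quadratic_objective


def dense_bfgs_apply(pairs, grad):
    """Dense inverse-Hessian recursion (the explicit update rule) on grad."""
    s_new, y_new = pairs[-1]
    H = np.eye(len(grad)) * (s_new @ y_new) / (y_new @ y_new)
    for s, y in pairs:
        rho = 1.0 / (y @ s)
        V = np.eye(len(grad)) - rho * np.outer(y, s)
        H = V.T @ H @ V + rho * np.outer(s, s)
    return H @ grad


def make_image(spacing):
    return Image3D(np.zeros((4, 4, 4)), spacing=spacing, origin=[0, 0, 0],
                   direction=np.eye(3))


class TestGDStep:
    def test_zero_gradient_leaves_mu(self):
        st = OptimizerState(mu=np.arange(6.0))
        gd_step(st, np.zeros(6))
        assert np.array_equal(st.mu, np.arange(6.0))
        assert st.k == 1

    def test_unit_gradient_step(self):
        st = OptimizerState(mu=np.zeros(6))
        st.lam = 1.0
        gd_step(st, np.array([1.0, 0, 0, 0, 0, 0]))
        assert np.array_equal(st.mu, [-1, 0, 0, 0, 0, 0])

    def test_nonfinite_gradient_fails(self):
        st = OptimizerState(mu=np.zeros(6))
        gd_step(st, np.array([np.nan] * 6))
        assert st.status == "failed"

    def test_monotone_decrease_on_quadratic_with_stable_step(self):
        D = np.array([1.0, 2, 3, 4, 5, 6])
        st = OptimizerState(mu=np.ones(6))
        st.lam = 1.9 / D.max()  # < 2/L: descent guaranteed
        vals = []
        for _ in range(50):
            vals.append(0.5 * float(st.mu @ (D * st.mu)))
            gd_step(st, D * st.mu)
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestComputeDelta:
    def test_unit_spacing_gives_one(self):
        assert compute_delta(make_image([1, 1, 1]),
                             make_image([1, 1, 1])) == 1.0

    def test_single_image_mean_spacing(self):
        # clinical CBCT spacing: mean(0.12, 0.12, 0.5) mm
        assert compute_delta(make_image([0.12, 0.12, 0.5])) == pytest.approx(
            0.2467, abs=1e-4)

    def test_pair_mean_and_symmetry(self):
        a, b = make_image([0.12, 0.12, 0.5]), make_image([0.12, 0.12, 0.3])
        assert compute_delta(a, b) == pytest.approx(1.28 / 6)
        assert compute_delta(a, b) == compute_delta(b, a)


class TestStepSizeSequence:
    def test_first_iteration_is_unity(self):
        lam, _ = step_size_sequence(0, 0.0, 20.0, 0.5)
        assert lam == 1.0

    def test_direct_substitution(self):
        # t_k = 0, A = 20 -> lam = eta / (1/20 + 1) = 20 eta / 21
        eta = 0.7
        lam, _ = step_size_sequence(1, 0.0, 20.0, eta)
        assert lam == pytest.approx(20 * eta / 21)

    def test_nonincreasing_when_t_grows(self):
        eta, A = 0.9, 20.0
        lams = [step_size_sequence(k, float(t), A, eta)[0]
                for k, t in enumerate(range(0, 40, 2))]
        assert all(b <= a for a, b in zip(lams[1:], lams[2:]))

    def test_anticorrelated_gradients_grow_t(self):
        g = np.ones(6)
        _, t_up = step_size_sequence(2, 0.0, 20.0, 1.0, grad_prev=g,
                                     grad_prev2=-g)
        _, t_dn = step_size_sequence(2, 0.0, 20.0, 1.0, grad_prev=g,
                                     grad_prev2=g)
        assert t_up > t_dn


class TestLBFGS:
    def test_empty_memory_returns_gradient(self):
        g = np.array([1.0, -2, 3, 0, 1, -1])
        assert np.array_equal(lbfgs_two_loop(LBFGSMemory(), g), g)

    def test_single_pair_matches_dense_update(self):
        rng = np.random.default_rng(40)
        mem = LBFGSMemory()
        s = rng.normal(size=6)
        y = s + 0.1 * rng.normal(size=6)
        assert mem.push(s, y)
        g = rng.normal(size=6)
        assert np.allclose(lbfgs_two_loop(mem, g),
                           dense_bfgs_apply([(s, y)], g), atol=1e-12)

    def test_two_loop_equals_dense_recursion_on_random_states(self):
        """Oracle equivalence over 100 random memory states."""
        rng = np.random.default_rng(41)
        worst = 0.0
        for _ in range(100):
            A = rng.normal(size=(6, 6))
            A = A @ A.T + 0.5 * np.eye(6)  # SPD map: bounded curvature
            mem = LBFGSMemory(capacity=5)
            pairs = []
            for _ in range(rng.integers(1, 6)):
                s = rng.normal(size=6)
                y = A @ s
                if mem.push(s, y):
                    pairs.append((s, y))
            g = rng.normal(size=6)
            err = np.abs(lbfgs_two_loop(mem, g)
                         - dense_bfgs_apply(pairs, g)).max()
            worst = max(worst, err)
        assert worst < 1e-12

    def test_exact_quadratic_memory_recovers_inverse_hessian(self):
        # conjugate (here: coordinate) steps with exact curvature pairs of
        # 0.5 mu'D mu rebuild the inverse Hessian, as exact BFGS steps on a
        # quadratic would
        D = np.array([1.0, 2, 4, 8, 16, 32])
        mem = LBFGSMemory(capacity=6)
        for i in range(6):
            s = np.zeros(6)
            s[i] = 1.0
            mem.push(s, D * s)
        g = np.random.default_rng(42).normal(size=6)
        assert np.allclose(lbfgs_two_loop(mem, g), g / D, atol=1e-8)

    def test_nonpositive_curvature_pairs_skipped(self):
        mem = LBFGSMemory()
        s = np.ones(6)
        assert not mem.push(s, -s)
        assert len(mem) == 0


class TestNoiseFactor:
    def _objective(self, g_true, sigma):
        def evaluate(mu, plan):
            rng = np.random.default_rng(int(plan) % (2 ** 31 - 1))
            return MetricEvaluation(value=0.0,
                                    gradient=g_true + rng.normal(0, sigma, 6),
                                    n_valid=1)
        return StochasticObjective(evaluate=evaluate,
                                   make_plan=lambda t: int(t))

    def test_noise_free_objective_gives_unity(self):
        obj = self._objective(np.array([1.0, 2, 3, 4, 5, 6]), 0.0)
        assert estimate_noise_factor(obj, np.zeros(6), 10) == pytest.approx(1.0)

    def test_pure_noise_objective_tends_to_zero(self):
        obj = self._objective(np.zeros(6), 1.0)
        eta = estimate_noise_factor(obj, np.zeros(6), 200)
        assert eta < 0.05

    def test_known_variance_matches_closed_form(self):
        g = np.array([2.0, -1, 3, 0.5, -2, 1])
        sigma = 1.0
        # closed form: |g|^2 / (|g|^2 + 6 sigma^2)
        expected = (g @ g) / (g @ g + 6 * sigma ** 2)
        obj = self._objective(g, sigma)
        etas = [estimate_noise_factor(obj, np.zeros(6), 50, seed=s)
                for s in range(0, 5000, 1000)]
        assert np.mean(etas) == pytest.approx(expected, rel=0.10)


class TestPreconditioner:
    def test_zero_gradients_degenerate_to_delta_over_epsilon(self):
        obj = make_quadratic_objective(np.zeros(6))
        pre = estimate_preconditioner(obj, np.ones(6), delta=0.5,
                                      epsilon=1e-6, n_probes=3)
        assert np.allclose(pre.diag, 0.5 / 1e-6)

    def test_delta_scales_linearly(self):
        obj = make_quadratic_objective(np.arange(1.0, 7.0), noise_sigma=0.1)
        p1 = estimate_preconditioner(obj, np.ones(6), delta=1.0, n_probes=5)
        p2 = estimate_preconditioner(obj, np.ones(6), delta=2.0, n_probes=5)
        assert np.allclose(p2.diag, 2 * p1.diag)

    def test_translation_jacobian_columns_have_unit_norm(self):
        from cochreg.optimizers import jacobian_column_norms
        rng = np.random.default_rng(43)
        norms = jacobian_column_norms(np.zeros(3), rng.uniform(-5, 5, (50, 3)))
        assert np.allclose(norms[3:], 1.0, atol=1e-12)


class TestRunsOnQuadratics:
    D_ILL = np.array([1.0, 3.0, 10.0, 30.0, 60.0, 100.0])  # condition 100
    D_MILD = np.array([0.5, 0.8, 1.0, 1.2, 1.4, 1.5])

    def _config(self, **kw):
        base = dict(max_iterations=2000, delta=1.0, seed=1,
                    step_tol_factor=1e-9)
        base.update(kw)
        return OptimizerConfig(**base)

    @staticmethod
    def _first_below(state, tol):
        return next((r["k"] for r in state.trace if r["value"] < tol), None)

    def test_asgd_converges_on_noise_free_quadratic(self):
        obj = make_quadratic_objective(self.D_MILD)
        st = asgd_run(obj, np.ones(6), self._config(max_iterations=100))
        assert np.linalg.norm(st.mu) < 1e-4

    def test_fasgd_agrees_with_asgd_and_is_cheaper(self):
        obj = make_quadratic_objective(self.D_MILD)
        cfg = self._config(max_iterations=100)
        st_a = asgd_run(obj, np.ones(6), cfg)
        st_f = fasgd_run(obj, np.ones(6), cfg)
        assert np.linalg.norm(st_a.mu - st_f.mu) < 1e-3
        assert st_f.eval_count / st_f.k < st_a.eval_count / st_a.k

    def test_slbfgs_beats_plain_sgd_on_ill_conditioned_quadratic(self):
        obj = make_quadratic_objective(self.D_ILL)
        st = slbfgs_run(obj, np.ones(6), self._config())
        k_lbfgs = self._first_below(st, 1e-6)
        # plain SGD baseline at the stable fixed step 1/L
        state = OptimizerState(mu=np.ones(6))
        state.lam = 1.0 / self.D_ILL.max()
        k_sgd = None
        for k in range(2000):
            if 0.5 * float(state.mu @ (self.D_ILL * state.mu)) < 1e-6:
                k_sgd = k
                break
            gd_step(state, self.D_ILL * state.mu)
        assert k_lbfgs is not None and k_sgd is not None
        assert k_lbfgs < k_sgd

    def test_fpsgd_beats_plain_sgd_on_ill_conditioned_quadratic(self):
        obj = make_quadratic_objective(self.D_ILL)
        st = fpsgd_run(obj, np.ones(6), self._config())
        k_pre = self._first_below(st, 1e-6)
        assert k_pre is not None and k_pre < 100

    def test_identity_preconditioner_fixed_step_reduces_to_sgd(self):
        from cochreg.optimizers import PreconditionerState
        # mu_{k+1} = mu_k - lam M g with M = I is the plain SGD update
        pre = PreconditionerState(diag=np.ones(6), delta=1.0)
        mu = np.ones(6)
        lam = 0.01
        g = self.D_ILL * mu
        assert np.allclose(mu - lam * (pre.diag * g), mu - lam * g)

    def test_all_optimizers_fixed_point_at_zero_gradient(self):
        obj = make_quadratic_objective(np.zeros(6))
        for run in (asgd_run, fasgd_run, slbfgs_run, fpsgd_run):
            st = run(obj, np.full(6, 0.7), self._config(max_iterations=20))
            assert np.allclose(st.mu, 0.7, atol=1e-12), run.__name__

    def test_seeded_determinism_of_traces(self):
        obj = make_quadratic_objective(self.D_MILD, noise_sigma=0.3)
        cfg = self._config(max_iterations=50)
        for run in (asgd_run, fasgd_run, slbfgs_run, fpsgd_run):
            t1 = run(obj, np.ones(6), cfg).trace
            t2 = run(obj, np.ones(6), cfg).trace
            assert t1 == t2, run.__name__

    def test_overlap_loss_mid_run_sets_failed(self):
        from cochreg.metrics import MetricOverlapError

        calls = {"n": 0}

        def evaluate(mu, plan):
            calls["n"] += 1
            if calls["n"] > 4:
                raise MetricOverlapError("overlap lost")
            mu = np.asarray(mu, float)
            return MetricEvaluation(value=float(mu @ mu), gradient=2 * mu,
                                    n_valid=1)

        obj = StochasticObjective(evaluate=evaluate, make_plan=lambda t: int(t))
        for run in (asgd_run, fasgd_run, slbfgs_run, fpsgd_run):
            calls["n"] = 0
            st = run(obj, np.ones(6), self._config(max_iterations=30))
            assert st.status == "failed", run.__name__

    def test_metric_blowup_detected_as_failure(self):
        # gradient pointing AWAY from the minimum: value grows every step
        def evaluate(mu, plan):
            mu = np.asarray(mu, float)
            return MetricEvaluation(value=float(mu @ mu),
                                    gradient=-4 * mu, n_valid=1)
        obj = StochasticObjective(evaluate=evaluate, make_plan=lambda t: int(t))
        st = asgd_run(obj, np.ones(6), self._config(max_iterations=40))
        assert st.status == "failed"


class TestDisplacementCap:
    def test_roi_corners_never_move_more_than_delta(self, quadratic_factory):
        rng = np.random.default_rng(44)
        corners = rng.uniform(-6, 6, (8, 3))
        base = quadratic_factory(np.array([50.0, 40, 30, 20, 10, 60]),
                                 noise_sigma=1.0)
        obj = StochasticObjective(evaluate=base.evaluate,
                                  make_plan=base.make_plan,
                                  corner_points=corners,
                                  center=np.zeros(3))
        delta = 0.25
        mu0 = np.full(6, 0.5)
        cfg = OptimizerConfig(max_iterations=40, delta=delta, seed=2,
                              step_tol_factor=1e-12)
        for run in (asgd_run, fasgd_run, slbfgs_run, fpsgd_run):
            st = run(obj, mu0, cfg)
            mus = [mu0] + [np.array(row["mu"]) for row in st.trace]
            for a, b in zip(mus, mus[1:]):
                Ta = RigidTransform(parameters=a, center=np.zeros(3))
                Tb = RigidTransform(parameters=b, center=np.zeros(3))
                disp = np.linalg.norm(transform_points(Tb, corners)
                                      - transform_points(Ta, corners), axis=1)
                assert disp.max() <= delta * (1 + 1e-9), run.__name__
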