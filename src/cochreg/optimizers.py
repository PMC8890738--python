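"""The optimiser family for stochastic rigid registration.

All optimisers minimise a stochastic objective: at each iteration a fresh
random subset of voxels is drawn and the similarity metric plus its
6-parameter gradient are evaluated on it.  The family:

* ``gd_step`` — one plain gradient-descent update (building block);
* ``asgd_run`` — adaptive SGD: the step length is driven by delta, the
  maximum voxel displacement allowed per iteration, and a sigmoid
  time-adaptation of the decay; the noise factor is re-estimated every
  iteration from an extra independent gradient probe;
* ``fasgd_run`` — the fast variant: the noise factor and the
  displacement-to-step conversion constant are frozen at their initial
  estimates, halving the per-iteration evaluation count;
* ``slbfgs_run`` — stochastic limited-memory BFGS: quasi-Newton search
  directions from a bounded history of (parameter, gradient) difference
  pairs, with curvature pairs computed on a shared sample plan;
* ``fpsgd_run`` — preconditioned SGD: a positive diagonal preconditioner
  estimated once from the voxel-displacement distribution rescales the
  gradient.

Every optimiser enforces the displacement cap: no accepted step may move any
corner of the region of interest by more than delta mm.  Parameter scaling
(rotations x ROI half-diagonal) is applied internally so a unit step in any
scaled parameter displaces edge voxels comparably.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .metrics import MetricEvaluation, MetricOverlapError, DegenerateIntensityError
from .rigid_transform import RigidTransform, transform_points
from .volume_model import Image3D

__all__ = [
    "OptimizerConfig",
    "OptimizerState",
    "StochasticObjective",
    "LBFGSMemory",
    "PreconditionerState",
    "gd_step",
    "compute_delta",
    "asgd_run",
    "fasgd_run",
    "slbfgs_run",
    "fpsgd_run",
    "lbfgs_two_loop",
    "estimate_noise_factor",
    "estimate_preconditioner",
    "step_size_sequence",
    "OPTIMIZERS",
]


# ---------------------------------------------------------------------------
# Shared state and configuration
# ---------------------------------------------------------------------------

@dataclass
class StochasticObjective:
    """A stochastic objective the optimisers can drive.

    ``evaluate(mu, plan)`` returns a :class:`MetricEvaluation` for parameter
    vector ``mu`` on the given sample plan (any hashable token for synthetic
    objectives).  ``make_plan(tag)`` draws the plan for an integer tag;
    distinct tags give independent draws, equal tags identical ones —
    which is what lets s-LBFGS evaluate two parameter vectors on the SAME
    subset.  ``corner_points`` (8x3 world mm) and ``center`` carry the ROI
    geometry used for the displacement cap; when absent the cap falls back
    to the parameter-space step norm.
    """

    evaluate: Callable[[np.ndarray, object], MetricEvaluation]
    make_plan: Callable[[int], object]
    corner_points: Optional[np.ndarray] = None
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class OptimizerConfig:
    max_iterations: int = 100
    delta: float = 1.0               # max voxel displacement per step, mm
    scales: np.ndarray = field(default_factory=lambda: np.ones(6))
    memory: int = 5                  # L-BFGS history capacity
    A: float = 20.0                  # decay speed factor
    epsilon: float = 1e-12
    seed: int = 0
    noise_probes: int = 5            # initial probes for eta / preconditioner
    sigmoid_gain: float = 5.0        # scaling of the gradient-correlation arg
    step_tol_factor: float = 0.01    # early stop: step disp < factor * delta
    patience: int = 5                # ... for this many consecutive iterations
    fail_metric_factor: float = 2.0  # failed if final value > factor * initial

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float).reshape(6)


@dataclass
class OptimizerState:
    mu: np.ndarray
    k: int = 0
    lam: float = 1.0
    status: str = "running"
    trace: list = field(default_factory=list)
    eval_count: int = 0
    initial_value: float = np.nan
    final_value: float = np.nan

    def log(self, value: float, step_norm: float, n_valid: int,
            mu=None) -> None:
        row = {"k": self.k, "value": value, "lam": self.lam,
               "step_norm": step_norm, "n_valid": n_valid}
        if mu is not None:
            row["mu"] = tuple(np.asarray(mu, dtype=float))
        self.trace.append(row)


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def gd_step(state: OptimizerState, grad: np.ndarray) -> OptimizerState:
    """One plain gradient-descent update mu <- mu - lam * grad."""
    grad = np.asarray(grad, dtype=float).reshape(6)
    if not np.all(np.isfinite(grad)):
        state.status = "failed"
        return state
    state.mu = state.mu - state.lam * grad
    state.k += 1
    return state


def compute_delta(fixed: Image3D, moving: Optional[Image3D] = None) -> float:
    """Maximum per-iteration voxel displacement: the mean voxel spacing.

    The mean is taken over all spacing components of the pair (six values,
    symmetric in image order), or over one image's three when only one is
    given.
    """
    comps = list(fixed.spacing)
    if moving is not None:
        comps += list(moving.spacing)
    return float(np.mean(comps))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def step_size_sequence(k: int, t_prev: float, A: float, eta: float,
                       grad_prev: Optional[np.ndarray] = None,
                       grad_prev2: Optional[np.ndarray] = None,
                       M: Optional[np.ndarray] = None,
                       sign: float = -1.0, gain: float = 5.0):
    """Non-increasing step-size schedule with sigmoid time adaptation.

    Returns ``(lam_k, t_k)``.  ``lam_0 = 1``; for k > 0,
    ``lam_k = eta / ((t_k + 1)/A + 1)`` where the time variable accumulates
    ``sigmoid(sign * <g_{k-1}, M g_{k-2}>)`` (correlation normalised to
    [-1, 1] and scaled by ``gain``).  With ``sign = -1``, positively
    correlated successive gradients (consistent descent) keep t small and
    the step large; anticorrelated gradients (oscillation around the
    minimum) drive t up and the step down.
    """
    t_k = t_prev
    if k > 1 and grad_prev is not None and grad_prev2 is not None:
        m = M if M is not None else np.ones(len(grad_prev))
        num = float(grad_prev @ (m * grad_prev2))
        den = (np.linalg.norm(np.sqrt(m) * grad_prev)
               * np.linalg.norm(np.sqrt(m) * grad_prev2))
        corr = num / den if den > 0 else 0.0
        t_k = max(0.0, t_prev + float(_sigmoid(sign * gain * corr)))
    lam = 1.0 if k == 0 else eta / ((t_k + 1.0) / A + 1.0)
    return lam, t_k


class LBFGSMemory:
    """Bounded history of (s, y) = (mu_{i+1}-mu_i, g_{i+1}-g_i) pairs.

    Pairs violating the curvature condition ``y.s > 0`` (within a relative
    floor) are skipped, which keeps the implied inverse-Hessian
    approximation positive definite without damping.
    """

    def __init__(self, capacity: int = 5):
        if capacity < 1:
            raise ValueError("memory capacity must be >= 1")
        self.capacity = capacity
        self.pairs: deque = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self.pairs)

    def push(self, s: np.ndarray, y: np.ndarray) -> bool:
        s = np.asarray(s, dtype=float)
        y = np.asarray(y, dtype=float)
        if y @ s <= 1e-12 * np.linalg.norm(y) * np.linalg.norm(s):
            return False
        self.pairs.append((s, y))
        return True


def lbfgs_two_loop(memory: LBFGSMemory, grad: np.ndarray) -> np.ndarray:
    """H^{-1} @ grad via the standard two-loop recursion.

    The initial inverse-Hessian is ``gamma * I`` with
    ``gamma = (s.y)/(y.y)`` from the newest stored pair; with an empty
    memory the result is the gradient itself (identity scaling).
    """
    q = np.asarray(grad, dtype=float).copy()
    pairs = list(memory.pairs)
    if not pairs:
        return q
    alphas = []
    for s, y in reversed(pairs):
        rho = 1.0 / (y @ s)
        a = rho * (s @ q)
        q -= a * y
        alphas.append((a, rho, s, y))
    s_new, y_new = pairs[-1]
    gamma = (s_new @ y_new) / (y_new @ y_new)
    r = gamma * q
    for a, rho, s, y in reversed(alphas):
        b = rho * (y @ r)
        r += (a - b) * s
    return r


# ---------------------------------------------------------------------------
# Noise factor and preconditioner estimation
# ---------------------------------------------------------------------------

def estimate_noise_factor(objective: StochasticObjective, mu0: np.ndarray,
                          n_probes: int = 5, seed: int = 0,
                          M: Optional[np.ndarray] = None) -> float:
    """Estimate the noise factor eta in [0, 1] from repeated gradient draws.

    eta = E|g' M g| / (E|g' M g| + E|eps' M eps|): the mean of the probes
    approximates the exact gradient g, the residuals approximate the
    stochastic noise eps.  A noise-free objective gives eta = 1; a
    pure-noise objective tends to 0 as probes grow.
    """
    if n_probes < 2:
        raise ValueError("need at least 2 probes")
    grads = []
    for r in range(n_probes):
        plan = objective.make_plan(seed + 900_000 + r)
        grads.append(objective.evaluate(np.asarray(mu0, float), plan).gradient)
    grads = np.array(grads)
    m = M if M is not None else np.ones(grads.shape[1])
    gbar = grads.mean(axis=0)
    signal = abs(float(gbar @ (m * gbar)))
    eps = grads - gbar
    noise = float(np.mean(np.einsum("ri,i,ri->r", eps, m, eps)))
    # residuals of n probes around their own mean underestimate the noise
    # by (n-1)/n; correct to the unbiased scale
    noise *= n_probes / (n_probes - 1)
    if signal + noise <= 0:
        warnings.warn("degenerate gradient probes; eta set to 1", stacklevel=2)
        return 1.0
    return signal / (signal + noise)


@dataclass
class PreconditionerState:
    diag: np.ndarray
    delta: float
    eta: float = 1.0
    A: float = 20.0
    t_k: float = 0.0
    epsilon: float = 1e-12

    def __post_init__(self):
        self.diag = np.asarray(self.diag, dtype=float).reshape(-1)
        if np.any(self.diag <= 0):
            raise ValueError("preconditioner diagonal must be positive")


def estimate_preconditioner(objective: StochasticObjective, mu0: np.ndarray,
                            delta: float, epsilon: float = 1e-12,
                            n_probes: int = 5, seed: int = 0,
                            jac_col_norms: Optional[np.ndarray] = None,
                            ) -> PreconditionerState:
    """Diagonal preconditioner from the voxel-displacement distribution.

    Each diagonal entry is ``m_i = delta / (E[|J_i| |g_i|] +
    2 sqrt(Var[|J_i| |g_i|]) + epsilon)`` where ``|J_i|`` is the mean norm
    of the i-th transform-Jacobian column over sampled voxels (exactly 1 for
    the translation parameters) and ``g_i`` the i-th stochastic gradient
    component over probes.  Larger delta scales every entry linearly; zero
    gradients degenerate to ``delta / epsilon``.
    """
    if n_probes < 2:
        raise ValueError("need at least 2 probes")
    mu0 = np.asarray(mu0, dtype=float)
    a = np.ones(6) if jac_col_norms is None else np.asarray(jac_col_norms, float)
    X = []
    for r in range(n_probes):
        plan = objective.make_plan(seed + 800_000 + r)
        g = objective.evaluate(mu0, plan).gradient
        X.append(a * np.abs(g))
    X = np.array(X)
    mean = X.mean(axis=0)
    spread = 2.0 * np.sqrt(X.var(axis=0, ddof=1))
    diag = delta / (mean + spread + epsilon)
    return PreconditionerState(diag=diag, delta=delta, epsilon=epsilon)


def jacobian_column_norms(center: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Mean L2 norm of each rigid-Jacobian column over a point set."""
    from .rigid_transform import jacobian_wrt_parameters
    T = RigidTransform(center=center)
    J = jacobian_wrt_parameters(T, np.asarray(points, float).reshape(-1, 3))
    return np.linalg.norm(J, axis=1).mean(axis=0)


# ---------------------------------------------------------------------------
# The iteration engine
# ---------------------------------------------------------------------------

def _step_displacement(objective: StochasticObjective, mu_a, mu_b) -> float:
    """Max displacement of the ROI corners between two parameter vectors."""
    if objective.corner_points is None:
        return float(np.linalg.norm(np.asarray(mu_b) - np.asarray(mu_a)))
    Ta = RigidTransform(parameters=mu_a, center=objective.center)
    Tb = RigidTransform(parameters=mu_b, center=objective.center)
    pa = transform_points(Ta, objective.corner_points)
    pb = transform_points(Tb, objective.corner_points)
    return float(np.max(np.linalg.norm(pb - pa, axis=1)))


def _cap_step(objective: StochasticObjective, mu, dmu, delta: float):
    """Scale a raw step so the ROI corner displacement stays <= delta."""
    dmu = np.asarray(dmu, dtype=float)
    for _ in range(12):
        disp = _step_displacement(objective, mu, mu + dmu)
        if disp <= delta * (1 + 1e-12) or disp == 0.0:
            break
        dmu = dmu * (delta / disp)
    return dmu, _step_displacement(objective, mu, mu + dmu)


def _finish(state: OptimizerState, objective, config, mu_scaled, scales,
            status_if_running: str) -> OptimizerState:
    state.mu = mu_scaled / scales
    if state.status == "running":
        state.status = status_if_running
    # Failure surrogate: the metric got materially worse than where it began.
    if (state.status != "failed" and np.isfinite(state.initial_value)
            and np.isfinite(state.final_value)):
        ref = abs(state.initial_value) + 1e-12
        if (state.final_value - state.initial_value) > (
                config.fail_metric_factor - 1.0) * ref:
            state.status = "failed"
    return state


def _run_sgd_family(objective: StochasticObjective, mu0, config: OptimizerConfig,
                    mode: str) -> OptimizerState:
    """Shared driver for asgd / fasgd / fpsgd (first-order methods).

    All three step along the negative gradient scaled by a decaying step
    size; the displacement-to-step conversion constant ``a`` is calibrated
    from the first gradient so the initial step moves the ROI corners by
    about delta mm.

    mode: "asgd"  — the noise factor eta is re-estimated every iteration
                    from a second independent gradient probe, and the decay
                    clock adapts to the correlation of successive gradients;
          "fasgd" — eta and the adaptation are frozen: initial eta estimate,
                    deterministic decay clock (half a unit per iteration);
          "fpsgd" — a frozen diagonal preconditioner (estimated from the
                    voxel-displacement distribution before iteration 0)
                    rescales the gradient.
    """
    scales = config.scales
    mu = np.asarray(mu0, dtype=float) * scales  # scaled parameter space
    state = OptimizerState(mu=np.asarray(mu0, dtype=float))
    delta = config.delta
    t_k = 0.0
    g_prev = g_prev2 = None

    precond = None
    eta = 1.0
    conv_factor = None  # delta / displacement-rate of the descent direction
    eta_signal = eta_noise = None  # asgd running noise estimates
    quiet = 0

    try:
        if mode == "fpsgd":
            jn = None
            if objective.corner_points is not None:
                jn = jacobian_column_norms(objective.center,
                                           objective.corner_points)
                jn = jn / scales  # column norms in scaled parameter space
            precond = estimate_preconditioner(
                _scaled_view(objective, scales), mu, delta,
                epsilon=config.epsilon, n_probes=config.noise_probes,
                seed=config.seed, jac_col_norms=jn)
            state.eval_count += config.noise_probes
            eta = estimate_noise_factor(_scaled_view(objective, scales), mu,
                                        n_probes=config.noise_probes,
                                        seed=config.seed + 1, M=precond.diag)
            state.eval_count += config.noise_probes
        elif mode == "fasgd":
            eta = estimate_noise_factor(_scaled_view(objective, scales), mu,
                                        n_probes=config.noise_probes,
                                        seed=config.seed)
            state.eval_count += config.noise_probes

        for k in range(config.max_iterations):
            plan = objective.make_plan(config.seed + k)
            ev = objective.evaluate(mu / scales, plan)
            state.eval_count += 1
            g = ev.gradient / scales
            if mode == "asgd":
                probe = objective.make_plan(config.seed + 500_000 + k)
                ev2 = objective.evaluate(mu / scales, probe)
                state.eval_count += 1
                g2 = ev2.gradient / scales
                gbar = 0.5 * (g + g2)
                eps = 0.5 * (g - g2)
                sig, noi = float(gbar @ gbar), 2.0 * float(eps @ eps)
                eta_signal = sig if eta_signal is None else 0.9 * eta_signal + 0.1 * sig
                eta_noise = noi if eta_noise is None else 0.9 * eta_noise + 0.1 * noi
                tot = eta_signal + eta_noise
                eta = eta_signal / tot if tot > 0 else 1.0
                g = gbar
            if not np.all(np.isfinite(g)):
                state.status = "failed"
                break
            if k == 0:
                state.initial_value = ev.value
            state.final_value = ev.value

            if mode == "fpsgd":
                direction = -(precond.diag * g)
            else:
                # displacement-to-step conversion: calibrated once so the
                # initial full-trust step moves the ROI corners by ~delta
                if conv_factor is None:
                    rate = _step_displacement(objective, mu / scales,
                                              (mu - g) / scales)
                    conv_factor = delta / rate if rate > 0 else 0.0
                direction = -conv_factor * g

            if mode == "fasgd":
                # frozen adaptation: deterministic decay clock
                t_k = 0.5 * k
                lam = 1.0 if k == 0 else eta / ((t_k + 1.0) / config.A + 1.0)
            else:
                lam, t_k = step_size_sequence(
                    k, t_k, config.A, eta, grad_prev=g_prev,
                    grad_prev2=g_prev2,
                    M=None if precond is None else precond.diag,
                    gain=config.sigmoid_gain)
            state.lam = lam
            dmu_raw = lam * direction
            dmu, disp = _cap_step(objective, mu / scales,
                                  dmu_raw / scales, delta)
            mu = mu + dmu * scales
            state.k = k + 1
            state.log(ev.value, float(np.linalg.norm(dmu)), ev.n_valid,
                      mu=mu / scales)

            g_prev2, g_prev = g_prev, g
            quiet = quiet + 1 if disp < config.step_tol_factor * delta else 0
            if quiet >= config.patience:
                state.status = "converged"
                break
    except (MetricOverlapError, DegenerateIntensityError):
        state.status = "failed"
    return _finish(state, objective, config, mu, scales,
                   "converged" if state.status == "converged" else "max_iter")


def _scaled_view(objective: StochasticObjective, scales) -> StochasticObjective:
    """Objective over the scaled parameter space (for probe estimators)."""
    def evaluate(mu_scaled, plan):
        ev = objective.evaluate(np.asarray(mu_scaled) / scales, plan)
        return MetricEvaluation(value=ev.value, gradient=ev.gradient / scales,
                                n_valid=ev.n_valid)
    return StochasticObjective(evaluate=evaluate, make_plan=objective.make_plan,
                               corner_points=objective.corner_points,
                               center=objective.center)


def asgd_run(objective: StochasticObjective, mu0, config: OptimizerConfig) -> OptimizerState:
    """Adaptive stochastic gradient descent (fully re-estimated)."""
    return _run_sgd_family(objective, mu0, config, "asgd")


def fasgd_run(objective: StochasticObjective, mu0, config: OptimizerConfig) -> OptimizerState:
    """Fast ASGD: adaptation constants frozen at their initial estimates."""
    return _run_sgd_family(objective, mu0, config, "fasgd")


def fpsgd_run(objective: StochasticObjective, mu0, config: OptimizerConfig) -> OptimizerState:
    """Fast preconditioned SGD: mu <- mu - lam_k M grad, M a frozen diagonal."""
    return _run_sgd_family(objective, mu0, config, "fpsgd")


def slbfgs_run(objective: StochasticObjective, mu0,
               config: OptimizerConfig) -> OptimizerState:
    """Stochastic limited-memory BFGS — the registration driver's default.

    Per iteration: a fresh sample plan gives the descent gradient; the
    quasi-Newton direction comes from the two-loop recursion over the stored
    history; the step is scaled by the decaying step-size sequence and
    capped at delta mm of ROI-corner displacement.  The curvature pair
    (g at mu_k, g at mu_{k+1}) is evaluated on one SHARED plan so the
    difference measures curvature rather than sampling noise.
    """
    scales = config.scales
    mu = np.asarray(mu0, dtype=float) * scales
    state = OptimizerState(mu=np.asarray(mu0, dtype=float))
    memory = LBFGSMemory(capacity=config.memory)
    t_k = 0.0
    g_prev = g_prev2 = None
    quiet = 0

    try:
        for k in range(config.max_iterations):
            plan = objective.make_plan(config.seed + k)
            ev = objective.evaluate(mu / scales, plan)
            state.eval_count += 1
            g = ev.gradient / scales
            if not np.all(np.isfinite(g)):
                state.status = "failed"
                break
            if k == 0:
                state.initial_value = ev.value
            state.final_value = ev.value

            direction = -lbfgs_two_loop(memory, g)
            lam, t_k = step_size_sequence(k, t_k, config.A, 1.0,
                                          grad_prev=g_prev, grad_prev2=g_prev2,
                                          gain=config.sigmoid_gain)
            if k == 0:
                # no curvature information yet: take a delta-sized probe step
                nrm = np.linalg.norm(direction)
                if nrm > 0:
                    direction = direction / nrm
            state.lam = lam
            dmu_raw = lam * direction
            dmu, disp = _cap_step(objective, mu / scales, dmu_raw / scales,
                                  config.delta)
            if not np.all(np.isfinite(dmu)):
                state.status = "failed"
                break
            mu_next = mu + dmu * scales

            # curvature pair on a shared plan (consistent sampling)
            shared = objective.make_plan(config.seed + 700_000 + k)
            g_a = objective.evaluate(mu / scales, shared).gradient / scales
            g_b = objective.evaluate(mu_next / scales, shared).gradient / scales
            state.eval_count += 2
            memory.push(mu_next - mu, g_b - g_a)

            mu = mu_next
            state.k = k + 1
            state.log(ev.value, float(np.linalg.norm(dmu)), ev.n_valid,
                      mu=mu / scales)
            g_prev2, g_prev = g_prev, g
            quiet = quiet + 1 if disp < config.step_tol_factor * config.delta else 0
            if quiet >= config.patience:
                state.status = "converged"
                break
    except (MetricOverlapError, DegenerateIntensityError):
        state.status = "failed"
    return _finish(state, objective, config, mu, scales,
                   "converged" if state.status == "converged" else "max_iter")


OPTIMIZERS = {
    "asgd": asgd_run,
    "fasgd": fasgd_run,
    "slbfgs": slbfgs_run,
    "fpsgd": fpsgd_run,
}
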