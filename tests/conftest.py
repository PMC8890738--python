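import numpy as np
import pytest

from cochreg.metrics import MetricEvaluation, draw_samples, intensity_window
from cochreg.optimizers import StochasticObjective
from cochreg.phantom import PhantomSpec, generate_phantom
from cochreg.pipeline import crop_to_cochlea
from cochreg.rigid_transform import (RigidTransform, build_virtual_domain,
                                     transform_points)


@pytest.fixture(scope="session")
def multimodal_pair():
    """CT-like / MR-like phantom pair with a known rigid misalignment.

    Returns a dict with the raw pair, the 10 mm crops, the virtual domain,
    precomputed intensity windows and the ground truth.
    """
    truth = RigidTransform(parameters=[0.03, -0.02, 0.05, 1.0, -0.8, 0.5])
    spec = PhantomSpec(modality_pair=("ct_like", "mr_like"),
                       true_transform=truth, noise_sigma=0.02, seed=3)
    fixed, moving, truth, flms, mlms = generate_phantom(spec)
    fc = crop_to_cochlea(fixed, [0, 0, 0], 10.0)
    mc = crop_to_cochlea(moving, transform_points(truth, [0, 0, 0]), 10.0)
    domain = build_virtual_domain(fc, mc, initial=truth)
    return {
        "fixed": fixed, "moving": moving, "truth": truth,
        "fixed_lms": flms, "moving_lms": mlms,
        "fixed_crop": fc, "moving_crop": mc, "domain": domain,
        "windows": (intensity_window(fc), intensity_window(mc)),
    }


@pytest.fixture(scope="session")
def monomodal_pair():
    """Noise-free CT/CT phantom pair (for MSE and fixed-point checks)."""
    truth = RigidTransform(parameters=[0.02, 0.04, -0.03, 0.6, -0.4, 0.9])
    spec = PhantomSpec(modality_pair=("ct_like", "ct_like"),
                       true_transform=truth, noise_sigma=0.0, seed=4)
    fixed, moving, truth, flms, mlms = generate_phantom(spec)
    fc = crop_to_cochlea(fixed, [0, 0, 0], 10.0)
    mc = crop_to_cochlea(moving, transform_points(truth, [0, 0, 0]), 10.0)
    domain = build_virtual_domain(fc, mc, initial=truth)
    return {
        "fixed": fixed, "moving": moving, "truth": truth,
        "fixed_lms": flms, "moving_lms": mlms,
        "fixed_crop": fc, "moving_crop": mc, "domain": domain,
    }


def make_quadratic_objective(D, noise_sigma=0.0):
    """Stochastic objective S(mu) = 0.5 mu' diag(D) mu (+ gradient noise).

    The plan token is an integer seed, so identical tokens give identical
    noise draws — mirroring how a frozen sample plan behaves.
    """
    D = np.asarray(D, dtype=float)

    def evaluate(mu, plan):
        mu = np.asarray(mu, dtype=float)
        g = D * mu
        if noise_sigma > 0:
            rng = np.random.default_rng(int(plan) % (2 ** 31 - 1))
            g = g + rng.normal(0, noise_sigma, len(mu))
        return MetricEvaluation(value=0.5 * float(mu @ (D * mu)),
                                gradient=g, n_valid=1)

    return StochasticObjective(evaluate=evaluate, make_plan=lambda t: int(t))


@pytest.fixture
def quadratic_factory():
    return make_quadratic_objective
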