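import numpy as np
import pytest

from cochreg.metrics import (MetricOverlapError, DegenerateIntensityError,
                             SamplePlan, draw_samples,
                             finite_difference_gradient, intensity_window,
                             interior_plan, joint_parzen_histogram,
                             mattes_mi_metric, mse_metric, _mi_bin_coords)
from cochreg.rigid_transform import RigidTransform, build_virtual_domain
from cochreg.volume_model import Image3D


def noise_image(seed, shape=(24, 24, 24), spacing=(1, 1, 1)):
    rng = np.random.default_rng(seed)
    return Image3D(rng.normal(500, 100, shape), spacing=spacing,
                   origin=[0, 0, 0], direction=np.eye(3))


class TestDrawSamples:
    def test_same_seed_identical_plan(self, multimodal_pair):
        dom = multimodal_pair["domain"]
        a = draw_samples(dom, 500, 7)
        b = draw_samples(dom, 500, 7)
        assert np.array_equal(a.points, b.points)

    def test_all_points_inside_domain(self, multimodal_pair):
        dom = multimodal_pair["domain"]
        plan = draw_samples(dom, 2000, 1)
        idx = (plan.points - dom.origin) @ dom.direction / dom.spacing
        assert np.all(idx >= -1e-9)
        assert np.all(idx <= np.array(dom.shape) - 1 + 1e-9)

    def test_empirical_mean_near_domain_centre(self, multimodal_pair):
        dom = multimodal_pair["domain"]
        n = 4000
        plan = draw_samples(dom, n, 5)
        centre = dom.origin + 0.5 * (np.array(dom.shape) - 1) * dom.spacing
        extent = (np.array(dom.shape) - 1) * dom.spacing
        sigma = extent / np.sqrt(12)  # sd of a uniform over the extent
        assert np.all(np.abs(plan.points.mean(axis=0) - centre)
                      < 3 * sigma / np.sqrt(n))

    def test_oversampling_warns_not_raises(self):
        img = noise_image(0, shape=(4, 4, 4))
        dom = build_virtual_domain(img, img)
        with pytest.warns(UserWarning, match="replacement"):
            draw_samples(dom, 1000, 0)

    def test_per_iteration_refresh_changes_points(self, multimodal_pair):
        dom = multimodal_pair["domain"]
        plan = draw_samples(dom, 100, 3, refresh_policy="per_iteration")
        assert not np.array_equal(plan.refresh(1).points, plan.points)
        fixed = draw_samples(dom, 100, 3, refresh_policy="fixed")
        assert np.array_equal(fixed.refresh(5).points, fixed.points)


class TestMSE:
    def test_self_similarity_is_zero(self, monomodal_pair):
        d = monomodal_pair
        plan = draw_samples(d["domain"], 1000, 2, refresh_policy="fixed")
        plan = interior_plan(plan, d["fixed_crop"], d["fixed_crop"],
                             RigidTransform())
        ev = mse_metric(d["fixed_crop"], d["fixed_crop"], RigidTransform(),
                        plan)
        assert ev.value == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ev.gradient, 0.0, atol=1e-9)

    def test_constant_offset_gives_squared_offset(self, monomodal_pair):
        d = monomodal_pair
        shifted = d["fixed_crop"].copy()
        shifted.intensities = shifted.intensities.astype(float) + 25.0
        plan = draw_samples(d["domain"], 1000, 3, refresh_policy="fixed")
        plan = interior_plan(plan, d["fixed_crop"], shifted, RigidTransform())
        ev = mse_metric(d["fixed_crop"], shifted, RigidTransform(), plan)
        assert ev.value == pytest.approx(625.0, rel=1e-9)

    def test_value_invariant_to_sample_order(self, monomodal_pair):
        d = monomodal_pair
        plan = draw_samples(d["domain"], 512, 4, refresh_policy="fixed")
        ev1 = mse_metric(d["fixed_crop"], d["moving_crop"], d["truth"], plan)
        shuffled = SamplePlan(points=plan.points[::-1], seed=plan.seed,
                              refresh_policy="fixed")
        ev2 = mse_metric(d["fixed_crop"], d["moving_crop"], d["truth"],
                         shuffled)
        assert ev1.value == pytest.approx(ev2.value, rel=1e-12)

    def test_deterministic_under_fixed_plan(self, monomodal_pair):
        d = monomodal_pair
        plan = draw_samples(d["domain"], 512, 5, refresh_policy="fixed")
        a = mse_metric(d["fixed_crop"], d["moving_crop"], d["truth"], plan)
        b = mse_metric(d["fixed_crop"], d["moving_crop"], d["truth"], plan)
        assert a.value == b.value
        assert np.array_equal(a.gradient, b.gradient)

    def test_total_overlap_loss_raises(self, monomodal_pair):
        d = monomodal_pair
        plan = draw_samples(d["domain"], 100, 6, refresh_policy="fixed")
        far = RigidTransform(parameters=[0, 0, 0, 500, 0, 0])
        with pytest.raises(MetricOverlapError):
            mse_metric(d["fixed_crop"], d["moving_crop"], far, plan)


class TestMattesMI:
    def test_histogram_is_normalised_probability(self, multimodal_pair):
        d = multimodal_pair
        plan = draw_samples(d["domain"], 2000, 7, refresh_policy="fixed")
        from cochreg.metrics import _sample_pair
        f, m, _, _ = _sample_pair(d["fixed_crop"], d["moving_crop"],
                                  d["truth"], plan)
        fbin, mcont, _, _ = _mi_bin_coords(f, m, d["windows"][0],
                                           d["windows"][1], 32)
        p = joint_parzen_histogram(fbin, mcont, 32)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(p >= 0)
        # marginals are proper distributions too
        assert p.sum(axis=0).sum() == pytest.approx(1.0, abs=1e-10)
        assert p.sum(axis=1).sum() == pytest.approx(1.0, abs=1e-10)

    def test_minimum_at_alignment_under_translation_scan(self, multimodal_pair):
        d = multimodal_pair
        plan = draw_samples(d["domain"], 3000, 8, refresh_policy="fixed")
        at_truth = mattes_mi_metric(d["fixed_crop"], d["moving_crop"],
                                    d["truth"], plan,
                                    windows=d["windows"]).value
        for axis in range(3):
            for off in (-2.0, -1.0, 1.0, 2.0):
                dp = np.zeros(6)
                dp[3 + axis] = off
                T = d["truth"].with_parameters(d["truth"].parameters + dp)
                misaligned = mattes_mi_metric(d["fixed_crop"],
                                              d["moving_crop"], T, plan,
                                              windows=d["windows"]).value
                assert at_truth < misaligned

    def test_independent_noise_has_near_zero_mi(self):
        a = noise_image(21, shape=(40, 40, 40))
        b = noise_image(22, shape=(40, 40, 40))
        dom = build_virtual_domain(a, b)
        plan = draw_samples(dom, 5000, 9, refresh_policy="fixed")
        ev = mattes_mi_metric(a, b, RigidTransform(), plan)
        assert abs(ev.value) < 0.05

    def test_constant_image_rejected(self):
        flat = Image3D(np.full((8, 8, 8), 7.0), spacing=[1, 1, 1],
                       origin=[0, 0, 0], direction=np.eye(3))
        with pytest.raises(DegenerateIntensityError):
            intensity_window(flat)

    def test_deterministic_under_fixed_plan(self, multimodal_pair):
        d = multimodal_pair
        plan = draw_samples(d["domain"], 1000, 10, refresh_policy="fixed")
        a = mattes_mi_metric(d["fixed_crop"], d["moving_crop"], d["truth"],
                             plan, windows=d["windows"])
        b = mattes_mi_metric(d["fixed_crop"], d["moving_crop"], d["truth"],
                             plan, windows=d["windows"])
        assert a.value == b.value
        assert np.array_equal(a.gradient, b.gradient)


class TestGradients:
    """Analytic gradients against the central finite-difference oracle."""

    def _offset_state(self, d, rng):
        doff = rng.uniform(0.4, 1.2, 3) * rng.choice([-1, 1], 3)
        roff = rng.uniform(0.03, 0.08, 3) * rng.choice([-1, 1], 3)
        T = d["truth"].with_parameters(
            d["truth"].parameters + np.concatenate([roff, doff]))
        plan = interior_plan(
            draw_samples(d["domain"], 2500, int(rng.integers(1e6)),
                         refresh_policy="fixed"),
            d["fixed_crop"], d["moving_crop"], T)
        return T, plan

    def test_fd_of_identical_images_at_identity_is_zero(self, monomodal_pair):
        d = monomodal_pair
        img = d["fixed_crop"].copy()
        img.intensities = img.intensities.astype(float) / 1000.0  # unit scale
        plan = draw_samples(d["domain"], 500, 11, refresh_policy="fixed")
        plan = interior_plan(plan, img, img, RigidTransform())

        def metric(T, p):
            return mse_metric(img, img, T, p)

        g = finite_difference_gradient(metric, RigidTransform(), plan, h=1e-6)
        assert np.allclose(g, 0.0, atol=1e-8)

    def test_mse_gradient_matches_finite_differences(self, monomodal_pair):
        d = monomodal_pair
        rng = np.random.default_rng(30)
        for _ in range(3):
            T, plan = self._offset_state(d, rng)

            def metric(TT, p):
                return mse_metric(d["fixed_crop"], d["moving_crop"], TT, p)

            g = metric(T, plan).gradient
            gfd = finite_difference_gradient(metric, T, plan, h=1e-6)
            assert np.linalg.norm(g - gfd) / np.linalg.norm(gfd) < 0.02

    def test_mi_gradient_matches_finite_differences(self, multimodal_pair):
        d = multimodal_pair
        rng = np.random.default_rng(31)
        for _ in range(3):
            T, plan = self._offset_state(d, rng)

            def metric(TT, p):
                return mattes_mi_metric(d["fixed_crop"], d["moving_crop"],
                                        TT, p, windows=d["windows"])

            g = metric(T, plan).gradient
            gfd = finite_difference_gradient(metric, T, plan, h=1e-6)
            assert np.linalg.norm(g - gfd) / np.linalg.norm(gfd) < 0.05
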