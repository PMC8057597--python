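"""Proximal subproblem solvers: Poisson update, OGS/MM, l_p/IRLS, fidelity."""

import numpy as np
import pytest

from poissontv.operators import forward_diff, second_order_diff
from poissontv.proximal import (
    group_weights, kl_divergence, lp_prox_irls, lp_smoothed_objective,
    objective_value, ogs_majorizer, ogs_prox, ogs_value, poisson_data_update,
)
import oracles


class TestPoissonDataUpdate:
    def test_zero_counts_give_positive_part(self, rng):
        hf = rng.normal(size=(6, 6))
        w = rng.normal(size=(6, 6))
        g = np.zeros((6, 6))
        lam, d1 = 2.0, 0.5
        t = hf - (w + lam) / d1
        x = poisson_data_update(hf, w, g, lam, d1)
        np.testing.assert_allclose(x, np.maximum(t, 0.0), atol=1e-12)

    def test_scalar_example(self):
        # lam=1, d1=1, g=2, Hf - w/d1 = 0: root of x^2 + x - 2 = 0
        x = poisson_data_update(np.array([[0.0]]), np.array([[0.0]]),
                                np.array([[2.0]]), 1.0, 1.0)
        assert x[0, 0] == pytest.approx(1.0)

    def test_vanishing_fidelity_limit(self, rng):
        hf = rng.uniform(1, 5, size=(4, 4))
        w = rng.normal(size=(4, 4))
        g = rng.uniform(0, 5, size=(4, 4))
        x = poisson_data_update(hf, w, g, 1e-12, 1.0)
        np.testing.assert_allclose(x, np.maximum(hf - w, 0.0), atol=1e-4)

    def test_matches_numeric_minimisation(self, rng):
        for _ in range(25):
            g = rng.uniform(0.0, 50.0)
            hf = rng.uniform(0.0, 50.0)
            w = rng.normal(scale=5.0)
            lam = rng.uniform(0.5, 300.0)
            d1 = rng.uniform(1e-3, 1.0)
            x = poisson_data_update(np.array([[hf]]), np.array([[w]]),
                                    np.array([[g]]), lam, d1)[0, 0]
            ref = oracles.poisson_pixel_minimize(g, hf - w / d1, lam, d1)
            assert x == pytest.approx(ref, rel=1e-8, abs=1e-10)

    def test_nonnegative_output(self, rng):
        x = poisson_data_update(rng.normal(size=(8, 8)),
                                rng.normal(size=(8, 8)) * 10,
                                rng.uniform(0, 9, size=(8, 8)), 3.0, 0.2)
        assert x.min() >= -1e-12

    def test_input_validation(self):
        g = np.array([[1.0]])
        with pytest.raises(ValueError):
            poisson_data_update(g, g, -g, 1.0, 1.0)
        with pytest.raises(ValueError):
            poisson_data_update(g, g, g, 0.0, 1.0)
        with pytest.raises(ValueError):
            poisson_data_update(g, g, g, 1.0, -1.0)


class TestGroupWeights:
    def test_single_element_groups(self, rng):
        u = rng.normal(size=(5, 5))
        eps = 1e-10
        np.testing.assert_allclose(group_weights(u, 1, eps),
                                   1.0 / np.sqrt(u ** 2 + eps))

    def test_interior_weight_of_ones(self):
        u = np.ones((9, 9))
        w = group_weights(u, 3, 1e-15)
        # every one of the 9 windows containing the centre has energy 9
        assert w[4, 4] == pytest.approx(3.0)

    def test_sign_invariance(self, rng):
        u = rng.normal(size=(6, 6))
        np.testing.assert_allclose(group_weights(u, 2), group_weights(-u, 2))

    def test_group_too_large_rejected(self):
        with pytest.raises(ValueError):
            group_weights(np.ones((4, 4)), 5)


class TestOGSProx:
    def test_zero_is_fixed_point(self):
        v = ogs_prox(np.zeros((6, 6)), 1.0, 3, 10)
        assert np.all(v == 0)

    def test_k1_converges_to_soft_threshold(self):
        v = ogs_prox(np.array([[5.0]]), 2.0, 1, 200)
        assert v[0, 0] == pytest.approx(3.0, abs=1e-6)

    def test_contraction_and_sign_preservation(self, rng):
        v0 = rng.normal(size=(8, 8))
        v = ogs_prox(v0, 0.7, 3, 20)
        assert np.all(np.abs(v) <= np.abs(v0) + 1e-15)
        assert np.all(v * v0 >= 0)

    def test_surrogate_descent_every_iteration(self, rng):
        for K in (2, 3):
            v0 = rng.normal(size=(6, 6))
            lam = 0.4
            v = v0.copy()
            prev = 0.5 * ((v - v0) ** 2).sum() + lam * ogs_value(v, K)
            for _ in range(15):
                v = v0 / (1.0 + lam * group_weights(v, K))  # one MM sweep
                cur = 0.5 * ((v - v0) ** 2).sum() + lam * ogs_value(v, K)
                assert cur <= prev + 1e-12
                prev = cur

    def test_matches_generic_convex_solver(self, rng):
        v0 = rng.normal(size=(6, 6))
        lam = 0.2
        mine = ogs_prox(v0, lam, 2, 500)
        ref = oracles.ogs_prox_lbfgs(v0, lam, 2)
        assert np.linalg.norm(mine - ref) / np.linalg.norm(ref) <= 1e-4

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ogs_prox(np.ones((4, 4)), 0.0, 2, 5)
        with pytest.raises(ValueError):
            ogs_prox(np.ones((4, 4)), 1.0, 2, 0)


class TestOGSValue:
    def test_zero_and_l1(self, rng):
        assert ogs_value(np.zeros((5, 5)), 3) == 0
        v = rng.normal(size=(5, 5))
        assert ogs_value(v, 1) == pytest.approx(np.abs(v).sum())

    def test_matches_brute_force_enumeration(self, rng):
        v = np.ones((5, 5))
        assert ogs_value(v, 3) == pytest.approx(oracles.brute_ogs_value(v, 3))
        v = rng.normal(size=(6, 6))
        for K in (2, 3, 4):
            assert ogs_value(v, K) == pytest.approx(
                oracles.brute_ogs_value(v, K), rel=1e-12)


class TestMajorizer:
    def test_majorizes_with_equality_at_center(self, rng):
        for K in (2, 3):
            for _ in range(100):
                v = rng.normal(size=(6, 6))
                u = rng.normal(size=(6, 6))
                assert ogs_majorizer(v, u, K) >= ogs_value(v, K) - 1e-10
                assert abs(ogs_majorizer(u, u, K) - ogs_value(u, K)) <= 1e-6


class TestLpProxIRLS:
    def test_fixed_points(self, rng):
        assert np.all(lp_prox_irls(np.zeros((4, 4)), 1.0, 0.5) == 0)
        z0 = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(lp_prox_irls(z0, 0.0, 0.5), z0)

    def test_contraction_and_sign(self, rng):
        z0 = rng.normal(size=(5, 5)) * 3
        z = lp_prox_irls(z0, 1.0, 0.3, n_irls=30)
        assert np.all(np.abs(z) <= np.abs(z0) + 1e-15)
        assert np.all(z * z0 >= 0)

    def test_smoothed_objective_descends(self, rng):
        z0 = rng.normal(size=(6, 6)) * 2
        lam, p, eps = 0.8, 0.1, 1e-6
        z = z0.copy()
        prev = lp_smoothed_objective(z, z0, lam, p, eps)
        for _ in range(20):
            z = z0 / (1.0 + lam * p * (z * z + eps) ** (p / 2.0 - 1.0))
            cur = lp_smoothed_objective(z, z0, lam, p, eps)
            assert cur <= prev + 1e-12
            prev = cur

    def test_scalar_against_grid_search(self, rng):
        for _ in range(10):
            z0 = rng.uniform(-3, 3)
            lam = rng.uniform(0.1, 1.5)
            p = 0.5
            z = float(lp_prox_irls(np.array([z0]), lam, p, 1e-6, 100)[0])
            gmin, locs = oracles.lp_grid_minima(z0, lam, p)
            zobj = 0.5 * (z - z0) ** 2 + lam * abs(z) ** p
            near = np.abs(locs - z).min() if locs.size else np.inf
            assert zobj <= gmin + 1e-3 or near < 1e-2

    def test_p_validation(self):
        for p in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                lp_prox_irls(np.ones(3), 1.0, p)


class TestKLDivergence:
    def test_identical_means_zero(self, rng):
        g = rng.uniform(0.5, 5, size=(6, 6))
        assert kl_divergence(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_zero_counts_leave_linear_term(self, rng):
        hf = rng.uniform(0, 5, size=(5, 5))
        assert kl_divergence(hf, np.zeros((5, 5))) == pytest.approx(hf.sum())

    def test_scalar_value(self):
        val = kl_divergence(np.array([[1.0]]), np.array([[2.0]]))
        assert val == pytest.approx(1 - 2 + 2 * np.log(2))

    def test_infinite_when_mean_vanishes_under_counts(self):
        with pytest.warns(RuntimeWarning):
            val = kl_divergence(np.array([[0.0]]), np.array([[1.0]]))
        assert val == np.inf


class TestObjectiveValue:
    def test_constant_image_with_exact_fit_is_zero(self):
        f = np.full((6, 6), 4.0)
        assert objective_value(f, f, f, lam=2.0, eta=1.5, p=0.1, K=3) == \
            pytest.approx(0.0, abs=1e-12)

    def test_term_isolation_matches_ogs_value(self, rng):
        f = rng.uniform(1, 5, size=(6, 6))
        g = f.copy()   # KL term vanishes; eta=0 kills the l_p term
        gh, gv = forward_diff(f)
        expected = ogs_value(gh, 3) + ogs_value(gv, 3)
        assert objective_value(f, g, f, lam=1.0, eta=0.0, p=0.1, K=3) == \
            pytest.approx(expected, rel=1e-12)

    def test_random_instance_against_straight_line_reevaluation(self, rng):
        f = rng.uniform(0.5, 4, size=(8, 8))
        g = rng.uniform(0.5, 4, size=(8, 8)).round()
        lam, eta, p, K = 2.0, 0.7, 0.3, 2
        hf = f  # treat blur as identity for this check
        kl = float((hf - g).sum() + (g[g > 0] * np.log(g[g > 0] / hf[g > 0])).sum())
        gh, gv = forward_diff(f)
        expected = (lam * kl
                    + oracles.brute_ogs_value(gh, K)
                    + oracles.brute_ogs_value(gv, K)
                    + eta * (np.abs(second_order_diff(f)) ** p).sum())
        assert objective_value(f, g, hf, lam=lam, eta=eta, p=p, K=K) == \
            pytest.approx(expected, rel=1e-10)
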