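"""Noise propagation: linear model, analytic covariance, full simulation."""

import numpy as np
import pytest
from scipy import stats

import armfitts as af
from armfitts.endpoint_model import (
    S0_REF,
    NoiseParams,
    draw_noise,
    endpoint_covariance,
    fit_rayleigh,
    gamma_coefficient,
    linear_endpoint_error,
    model_rmse,
    sample_torque_noise,
    simulate_endpoints_full,
)
from armfitts.trajectory import NormalizedTrajectory

from conftest import make_reach


def linear_samples(ntraj, params, k, D, n, seed):
    """Vectorized linear-model endpoint errors (n, 2)."""
    rng = np.random.default_rng(seed)
    z = draw_noise(ntraj.s.size, rng, n_trials=n)
    out = np.empty((n, 2))
    for i in range(n):
        r = linear_endpoint_error(ntraj, params, k, D, z[i])
        out[i] = r.dx, r.dy
    return out


class TestTorqueNoise:
    def test_zero_gain_and_zero_signal(self):
        grid = np.linspace(0, 1, 101)
        tau = np.ones((101, 2))
        assert np.allclose(
            sample_torque_noise(tau, NoiseParams(0, 0), grid, seed=1), 0.0
        )
        assert np.allclose(
            sample_torque_noise(np.zeros((101, 2)), NoiseParams(0.5, 0.5), grid, 1),
            0.0,
        )

    def test_per_sample_scale(self):
        # white-in-normalized-time with reference intensity S0_REF: per-sample
        # std is k * sqrt(S0_REF/ds) = 0.5 * sqrt(0.004/0.01) = 0.3162
        grid = np.linspace(0, 1, 101)
        tau = np.ones((101, 2))
        rng = np.random.default_rng(7)
        draws = np.concatenate(
            [sample_torque_noise(tau, NoiseParams(0.5, 0.5), grid, rng).ravel()
             for _ in range(10)]
        )
        expected = 0.5 * np.sqrt(S0_REF / 0.01)
        assert draws.std() == pytest.approx(expected, rel=0.05)

    def test_reproducible(self):
        grid = np.linspace(0, 1, 51)
        tau = np.random.default_rng(3).normal(size=(51, 2))
        a = sample_torque_noise(tau, NoiseParams(0.4, 0.9), grid, seed=11)
        b = sample_torque_noise(tau, NoiseParams(0.4, 0.9), grid, seed=11)
        assert np.array_equal(a, b)


class TestLinearPropagation:
    def test_zero_noise_zero_error(self, front_reach):
        p, _, nt = front_reach
        z = draw_noise(nt.s.size, np.random.default_rng(0))[0]
        r = linear_endpoint_error(nt, p, NoiseParams(0, 0), 0.5, z)
        assert r.dx == r.dy == r.gamma == r.W_model == 0.0

    def test_linearity_in_k(self, front_reach):
        p, _, nt = front_reach
        z = draw_noise(nt.s.size, np.random.default_rng(1))[0]
        r1 = linear_endpoint_error(nt, p, NoiseParams(0.2, 0.3), 0.5, z)
        r2 = linear_endpoint_error(nt, p, NoiseParams(0.4, 0.6), 0.5, z)
        assert r2.dx == pytest.approx(2 * r1.dx, rel=1e-12)
        assert r2.gamma == pytest.approx(2 * r1.gamma, rel=1e-12)

    def test_exact_inverse_proportionality(self, front_reach):
        p, _, nt = front_reach
        z = draw_noise(nt.s.size, np.random.default_rng(2))[0]
        k = NoiseParams(0.5, 0.7)
        products = [
            linear_endpoint_error(nt, p, k, D, z).W_model * D
            for D in (0.3, 0.5, 0.7)
        ]
        assert np.ptp(products) <= 1e-15
        r = linear_endpoint_error(nt, p, k, 0.5, z)
        assert r.W_model == pytest.approx(np.hypot(r.dx, r.dy), rel=1e-12)


class TestEndpointCovariance:
    def test_zero_noise(self, front_reach):
        p, _, nt = front_reach
        assert np.allclose(endpoint_covariance(nt, p, NoiseParams(0, 0), 0.5).sigma, 0)

    def test_matches_monte_carlo(self, front_reach):
        p, _, nt = front_reach
        k = NoiseParams(0.5, 0.7)
        sig = endpoint_covariance(nt, p, k, 0.5).sigma
        d = linear_samples(nt, p, k, 0.5, 100_000, seed=4)
        mc = np.cov(d, rowvar=False)
        assert np.linalg.norm(mc - sig) / np.linalg.norm(sig) <= 0.03

    def test_d2_scaling_exact(self, front_reach):
        p, _, nt = front_reach
        k = NoiseParams(0.3, 0.8)
        ref = endpoint_covariance(nt, p, k, 0.3).sigma * 0.3 ** 2
        for D in (0.5, 0.7):
            s = endpoint_covariance(nt, p, k, D).sigma * D ** 2
            assert np.allclose(s, ref, rtol=1e-13)


class TestGamma:
    def test_zero_noise(self, front_reach):
        p, _, nt = front_reach
        gb, draws = gamma_coefficient(nt, p, NoiseParams(0, 0), 10, seed=0)
        assert gb == 0.0 and np.all(draws == 0)

    def test_matches_gaussian_norm_quadrature(self, front_reach):
        # E gamma = E||N(0, D^2 Sigma)||, evaluated by Gauss-Hermite
        # quadrature in the covariance eigenbasis
        p, _, nt = front_reach
        k, D = NoiseParams(0.5, 0.7), 0.5
        gb, _ = gamma_coefficient(nt, p, k, n_draws=10_000, seed=5)
        evals = np.linalg.eigvalsh(D ** 2 * endpoint_covariance(nt, p, k, D).sigma)
        x, wx = np.polynomial.hermite_e.hermegauss(120)
        W = wx[:, None] * wx[None, :] / (2 * np.pi)
        R = np.hypot(
            np.sqrt(evals[0]) * x[:, None], np.sqrt(evals[1]) * x[None, :]
        )
        expected = float((W * R).sum())
        assert gb == pytest.approx(expected, rel=0.02)

    def test_monotone_in_gains(self, front_reach):
        p, _, nt = front_reach
        grid = [0.1, 0.3, 0.5, 0.7]
        for k2 in (0.2, 0.6):
            g = [gamma_coefficient(nt, p, NoiseParams(k1, k2), 200, seed=6)[0]
                 for k1 in grid]
            assert np.all(np.diff(g) > 0)
        for k1 in (0.2, 0.6):
            g = [gamma_coefficient(nt, p, NoiseParams(k1, k2), 200, seed=6)[0]
                 for k2 in grid]
            assert np.all(np.diff(g) > 0)


class TestFullSimulation:
    def test_noise_free_roundtrip(self, front_reach):
        p, traj, _ = front_reach
        dense = af.minimum_jerk_trajectory(
            af.forward_kinematics(traj.theta[0], p.L1, p.L2),
            af.forward_kinematics(traj.theta[-1], p.L1, p.L2),
            traj.D, 501, p,
        )
        samples = simulate_endpoints_full(dense, p, NoiseParams(0, 0), 3, seed=0)
        assert all(s.W <= 1e-6 for s in samples)

    def test_matches_linear_model_at_small_noise(self, mean_params, start_xy, lam):
        # at D = lambda the duration approximation drops out and the full
        # nonlinear simulation agrees with the linear propagation in mean W
        p, traj, nt = make_reach(mean_params, start_xy, "front", round(lam, 3))
        k = NoiseParams(0.1, 0.1)
        samples = simulate_endpoints_full(traj, p, k, 2000, seed=8)
        w_full = np.mean([s.W for s in samples])
        gb, _ = gamma_coefficient(nt, p, k, n_draws=4000, seed=9)
        assert w_full / (gb / traj.D) == pytest.approx(1.0, abs=0.10)

    def test_near_homogeneous_in_k_at_small_noise(self, mean_params, start_xy, lam):
        p, traj, _ = make_reach(mean_params, start_xy, "front", round(lam, 3))
        w1 = np.mean([s.W for s in
                      simulate_endpoints_full(traj, p, NoiseParams(0.05, 0.05),
                                              500, seed=10)])
        w2 = np.mean([s.W for s in
                      simulate_endpoints_full(traj, p, NoiseParams(0.10, 0.10),
                                              500, seed=10)])
        assert w2 / w1 == pytest.approx(2.0, abs=0.1)

    def test_agreement_with_linear_model_across_gain_grid(
        self, mean_params, start_xy, lam
    ):
        # at the study's scale the plant stays effectively linear: the
        # full-simulation/linear-model gap in mean W is ~3% and stays below
        # 5% over the whole plausible gain range
        p, traj, nt = make_reach(mean_params, start_xy, "front", round(lam, 3))
        for k in (0.1, 0.4, 0.8, 1.2):
            kp = NoiseParams(k, k)
            w_full = np.mean(
                [s.W for s in simulate_endpoints_full(traj, p, kp, 1500, seed=11)]
            )
            gb, _ = gamma_coefficient(nt, p, kp, n_draws=3000, seed=12)
            assert abs(w_full / (gb / traj.D) - 1.0) <= 0.05

    def test_interaction_toggle(self, mean_params, start_xy):
        # dropping Coriolis/centrifugal terms keeps the noise-free round
        # trip exact (both inverse and forward dynamics drop them) and
        # shifts the endpoint scatter by a modest, direction-dependent
        # amount (right-direction reach: ~5%)
        p, traj, _ = make_reach(mean_params, start_xy, "right", 0.5)
        s0 = simulate_endpoints_full(traj, p, NoiseParams(0, 0), 2, seed=0,
                                     include_interaction=False)
        assert all(s.W <= 1e-6 for s in s0)
        k = NoiseParams(0.5, 0.7)
        w_on = np.mean([s.W for s in
                        simulate_endpoints_full(traj, p, k, 1000, seed=13)])
        w_off = np.mean([s.W for s in
                         simulate_endpoints_full(traj, p, k, 1000, seed=13,
                                                 include_interaction=False)])
        assert 0.0 < abs(w_off / w_on - 1.0) <= 0.10


class TestRayleigh:
    def test_closed_form(self):
        assert fit_rayleigh([1, 1, 1, 1]) == pytest.approx(np.sqrt(0.5))

    def test_consistency(self):
        w = stats.rayleigh.rvs(scale=0.01, size=100_000,
                               random_state=np.random.default_rng(14))
        assert 0.0099 <= fit_rayleigh(w) <= 0.0101

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fit_rayleigh([0.1, -0.2])

    def test_isotropic_linear_model_is_rayleigh(self):
        # construct an exactly isotropic propagation: shoulder angle sweeps a
        # full turn at constant normalized torque, so the x/y integrands are
        # quadrature sinusoids and (dx, dy) is an isotropic Gaussian pair
        n = 101
        s = np.linspace(0, 1, n)
        ntraj = NormalizedTrajectory(
            s=s,
            theta_n=np.column_stack([2 * np.pi * s, np.full(n, 1.7)]),
            dtheta_n=np.zeros((n, 2)),
            ddtheta_n=np.zeros((n, 2)),
            tau_n=np.ones((n, 2)),
        )
        p = af.estimate_physical_params(0.282, 0.331)
        d = linear_samples(ntraj, p, NoiseParams(0.5, 0.5), 0.5, 3000, seed=15)
        cov = np.cov(d, rowvar=False)
        assert cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]) == pytest.approx(0, abs=0.05)
        assert cov[0, 0] / cov[1, 1] == pytest.approx(1.0, abs=0.1)
        w = np.hypot(d[:, 0], d[:, 1])
        sigma = fit_rayleigh(w)
        assert stats.kstest(w, "rayleigh", args=(0, sigma)).pvalue > 0.01


class TestModelRmse:
    def test_exact_model_means(self):
        gb = 0.004
        obs = np.array([[D, gb / D] for D in (0.35, 0.45, 0.55, 0.65)])
        assert model_rmse(obs, gb) == 0.0

    def test_constant_offset(self):
        gb = 0.004
        obs = np.array([[D, gb / D + 0.002] for D in (0.35, 0.45, 0.55, 0.65)])
        assert model_rmse(obs, gb) == pytest.approx(0.002)
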