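"""Confidence ellipses, the EDI pseudometric and the grid-search estimator."""

import numpy as np
import pytest
from scipy import stats

import armfitts as af
from armfitts.endpoint_model import NoiseParams, draw_noise, _rollout_noisy
from armfitts.noise_estimation import (
    ConfidenceEllipse,
    NoiseGainEstimator,
    ObservationGroup,
    confidence_ellipse,
    ellipse_difference_index,
)
from conftest import make_reach


class TestConfidenceEllipse:
    def test_isotropic_chi2_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, size=(100_000, 2))
        e = confidence_ellipse(x, level=0.95)
        expected = 0.01 * np.sqrt(stats.chi2.ppf(0.95, 2))
        assert e.semi_axes[0] == pytest.approx(expected, rel=0.02)
        assert e.semi_axes[1] == pytest.approx(expected, rel=0.02)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.01, size=(500, 2))
        e0 = confidence_ellipse(x)
        e1 = confidence_ellipse(x + [0.1, 0.0])
        assert np.allclose(e1.center, e0.center + [0.1, 0.0])
        assert e1.semi_axes == pytest.approx(e0.semi_axes, rel=1e-12)
        assert e1.angle == pytest.approx(e0.angle, abs=1e-12)

    def test_anisotropic_axes_and_angle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, [0.02, 0.01], size=(200_000, 2))
        e = confidence_ellipse(x)
        assert e.semi_axes[0] / e.semi_axes[1] == pytest.approx(2.0, rel=0.03)
        assert min(e.angle, np.pi - e.angle) == pytest.approx(0.0, abs=0.05)

    def test_degenerate(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            confidence_ellipse(line)
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))


def circle(r, center=(0.0, 0.0)):
    return ConfidenceEllipse(np.asarray(center, float), (r, r), 0.0)


class TestEDI:
    def test_identical_is_zero(self):
        e = ConfidenceEllipse(np.array([0.1, 0.2]), (0.03, 0.01), 0.4)
        assert ellipse_difference_index(e, e) == 0.0

    def test_translation(self):
        e1 = ConfidenceEllipse(np.array([0.0, 0.0]), (0.03, 0.01), 0.4)
        e2 = ConfidenceEllipse(np.array([0.05, 0.0]), (0.03, 0.01), 0.4)
        # small translation: each of the four points moves by less than d,
        # but orientation pairing keeps the sum at exactly 4 d here
        assert ellipse_difference_index(e1, e2) == pytest.approx(4 * 0.05)

    def test_concentric_circles(self):
        assert ellipse_difference_index(circle(0.03), circle(0.01)) == pytest.approx(
            4 * 0.02
        )

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            e1 = ConfidenceEllipse(rng.normal(size=2), tuple(sorted(
                rng.uniform(0.005, 0.05, 2), reverse=True)), rng.uniform(0, np.pi))
            e2 = ConfidenceEllipse(rng.normal(size=2), tuple(sorted(
                rng.uniform(0.005, 0.05, 2), reverse=True)), rng.uniform(0, np.pi))
            d12 = ellipse_difference_index(e1, e2)
            d21 = ellipse_difference_index(e2, e1)
            assert d12 == pytest.approx(d21, rel=1e-12)
            assert d12 >= 0

    def test_axis_sign_invariance(self):
        # flipping an axis orientation by pi describes the same ellipse
        e1 = ConfidenceEllipse(np.zeros(2), (0.03, 0.01), 0.3)
        e2 = ConfidenceEllipse(np.zeros(2), (0.03, 0.01), 0.3 + np.pi)
        assert ellipse_difference_index(e1, e2) == pytest.approx(0.0, abs=1e-12)


def make_groups(params, start, k_true, n_obs, seed, durations=(0.35, 0.55),
                directions=("front", "right")):
    """Observation groups simulated from the model itself."""
    groups = []
    rng = np.random.default_rng(seed)
    for d in directions:
        for D in durations:
            p, traj, _ = make_reach(params, start, d, D)
            samples = af.simulate_endpoints_full(
                traj, p, k_true, n_obs, seed=rng.integers(2 ** 31)
            )
            target = af.forward_kinematics(traj.theta[-1], p.L1, p.L2)
            pts = np.array([[s.dx, s.dy] for s in samples]) + target
            groups.append(ObservationGroup(
                endpoints=pts, desired=traj, direction=d, label=f"{d}-{D}",
                B=p.B,
            ))
    return groups


class TestNoiseGainEstimator:
    def test_self_match_gives_zero_edi(self, mean_params, start_xy):
        # observed endpoints generated with the exact z-stream of the
        # search's own simulation: total EDI vanishes at the true cell
        p, traj, _ = make_reach(mean_params, start_xy, "front", 0.5)
        seed = 5
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0, 0)))
        z = draw_noise(101, rng, n_trials=50)
        k_arr = np.broadcast_to([0.3, 0.3], (50, 2))
        pts = _rollout_noisy(traj, p, k_arr, z, 1e-3, True)
        group = ObservationGroup(endpoints=pts, desired=traj, direction="front",
                                 B=p.B)
        est = NoiseGainEstimator(k_min=0.2, k_max=0.4, k_step=0.1, n_sim=50,
                                 refine=False, seed=seed)
        est.fit([group], p)
        surf = est.result_.edi_surface
        i = int(np.argmin(np.abs(est.result_.k1_grid - 0.3)))
        assert surf[i, i] == pytest.approx(0.0, abs=1e-12)
        assert (est.k1_, est.k2_) == pytest.approx((0.3, 0.3))

    def test_recovery_within_one_step(self, mean_params, start_xy):
        # moderate-size recovery: truth simulated from the same model
        groups = make_groups(mean_params, start_xy, NoiseParams(0.4, 0.6),
                             n_obs=100, seed=17)
        est = NoiseGainEstimator(k_min=0.2, k_max=0.8, k_step=0.1, n_sim=100,
                                 refine=False, seed=3)
        est.fit(groups, mean_params)
        assert abs(est.k1_ - 0.4) <= 0.1
        assert abs(est.k2_ - 0.6) <= 0.1

    def test_surface_roughly_monotone_from_minimum(self, mean_params, start_xy):
        groups = make_groups(mean_params, start_xy, NoiseParams(0.4, 0.6),
                             n_obs=100, seed=17)
        est = NoiseGainEstimator(k_min=0.2, k_max=0.8, k_step=0.1, n_sim=100,
                                 refine=False, seed=3)
        est.fit(groups, mean_params)
        s = est.result_.edi_surface
        i, j = np.unravel_index(np.argmin(s), s.shape)
        steps = np.concatenate([
            np.diff(s[i, j:]), np.diff(s[i, :j + 1][::-1]),
            np.diff(s[i:, j]), np.diff(s[:i + 1, j][::-1]),
        ])
        assert np.mean(steps > 0) >= 0.8

    def test_deterministic_under_seed(self, mean_params, start_xy):
        groups = make_groups(mean_params, start_xy, NoiseParams(0.5, 0.5),
                             n_obs=30, seed=21, durations=(0.45,),
                             directions=("front",))
        kw = dict(k_min=0.3, k_max=0.7, k_step=0.2, n_sim=30, refine=False,
                  seed=9)
        s1 = NoiseGainEstimator(**kw).fit(groups, mean_params).result_.edi_surface
        s2 = NoiseGainEstimator(**kw).fit(groups, mean_params).result_.edi_surface
        assert np.array_equal(s1, s2)

    def test_functional_wrapper_and_surface_export(self, mean_params, start_xy):
        groups = make_groups(mean_params, start_xy, NoiseParams(0.5, 0.5),
                             n_obs=30, seed=21, durations=(0.45,),
                             directions=("front",))
        res = af.estimate_noise_params(
            groups, mean_params, k_min=0.3, k_max=0.7, k_step=0.2, n_sim=30,
            refine=False, seed=9,
        )
        assert res.best_k[0] in res.k1_grid and res.best_k[1] in res.k2_grid
        df = res.surface_frame()
        assert set(df.columns) == {"k1", "k2", "total_edi"}
        assert len(df) == res.edi_surface.size
        assert df["total_edi"].min() == res.edi_surface.min()

    def test_degenerate_groups(self, mean_params, start_xy):
        p, traj, _ = make_reach(mean_params, start_xy, "front", 0.5)
        bad = ObservationGroup(endpoints=np.zeros((5, 2)), desired=traj,
                               direction="front")
        est = NoiseGainEstimator(k_min=0.3, k_max=0.4, k_step=0.1, n_sim=10,
                                 refine=False)
        with pytest.raises(ValueError):
            est.fit([bad], mean_params)

    def test_refinement_brackets_coarse_optimum(self, mean_params, start_xy):
        groups = make_groups(mean_params, start_xy, NoiseParams(0.5, 0.5),
                             n_obs=60, seed=29, durations=(0.45,),
                             directions=("front", "left"))
        est = NoiseGainEstimator(k_min=0.3, k_max=0.7, k_step=0.1, n_sim=40,
                                 refine=True, refine_step=0.05, seed=2)
        est.fit(groups, mean_params)
        coarse = est.result_.best_k
        fine = est.result_.refined
        assert fine is not None
        # the final estimate sits inside the refinement window around the
        # coarse optimum, on the finer grid
        assert coarse[0] - 0.1 - 1e-9 <= est.k1_ <= coarse[0] + 0.1 + 1e-9
        assert coarse[1] - 0.1 - 1e-9 <= est.k2_ <= coarse[1] + 0.1 + 1e-9
        assert np.isclose(fine.k1_grid, est.k1_).any()
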