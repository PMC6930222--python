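"""Noise-gain estimation by confidence-ellipse matching.

The per-joint signal-dependent noise gains (k1, k2) are not directly
observable; they are estimated by simulation-based inference: for each
candidate (k1, k2) on a grid, endpoint scatters are simulated through the
full nonlinear dynamics for every (direction, duration-bin) condition and
compared with the observed scatters via the Ellipse Difference Index (EDI)
— the summed distance between the four axis endpoints (major and minor) of
the two 95% confidence ellipses.  The total EDI over all conditions is
minimized over the grid, optionally followed by a refinement pass on a
finer grid around the coarse optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .arm_dynamics import PhysicalParams
from .endpoint_model import NoiseParams, draw_noise, _rollout_noisy
from .trajectory import TimedTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceEllipse",
    "ObservationGroup",
    "GridSearchResult",
    "NoiseGainEstimator",
    "confidence_ellipse",
    "ellipse_axis_points",
    "ellipse_difference_index",
    "estimate_noise_params",
]


@dataclass
class ConfidenceEllipse:
    """Coverage ellipse of a 2-D scatter.

    ``semi_axes`` is (major, minor); ``angle`` the major-axis orientation
    in [0, pi); ``level`` the coverage probability.
    """

    center: np.ndarray
    semi_axes: tuple[float, float]
    angle: float
    level: float = 0.95

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        major, minor = self.semi_axes
        if not (major >= minor >= 0):
            raise ValueError("semi_axes must satisfy major >= minor >= 0")
        self.angle = float(self.angle) % np.pi


@dataclass
class ObservationGroup:
    """Observed endpoints and the matching desired trajectory for one
    (direction, duration-bin) condition."""

    endpoints: np.ndarray  # (n, 2) hand positions or errors, m
    desired: TimedTrajectory
    direction: str
    label: str = ""
    B: np.ndarray | None = None  # per-direction viscosity override

    def __post_init__(self) -> None:
        self.endpoints = np.atleast_2d(np.asarray(self.endpoints, dtype=float))
        if self.endpoints.shape[1] != 2:
            raise ValueError("endpoints must be (n, 2)")


@dataclass
class GridSearchResult:
    """EDI grid-search output; ``best_k`` attains the surface minimum."""

    k1_grid: np.ndarray
    k2_grid: np.ndarray
    edi_surface: np.ndarray  # (len(k1_grid), len(k2_grid))
    best_k: tuple[float, float]
    n_sim: int
    refined: "GridSearchResult | None" = None

    @property
    def k(self) -> NoiseParams:
        return NoiseParams(*self.best_k)

    def surface_frame(self):
        """Long-form (k1, k2, total_edi) table of the surface, for export."""
        import pandas as pd

        k1, k2 = np.meshgrid(self.k1_grid, self.k2_grid, indexing="ij")
        return pd.DataFrame(
            {"k1": k1.ravel(), "k2": k2.ravel(),
             "total_edi": self.edi_surface.ravel()}
        )


def confidence_ellipse(samples: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Coverage ellipse from the sample mean and covariance.

    Semi-axes are sqrt of the covariance eigenvalues scaled by the
    chi-square(2 dof) quantile at ``level``; the angle is the major
    eigenvector orientation.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] < 3 or x.shape[1] != 2:
        raise ValueError("need at least 3 two-dimensional samples")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate (collinear) sample covariance")
    scale = stats.chi2.ppf(level, df=2)
    major = float(np.sqrt(evals[1] * scale))
    minor = float(np.sqrt(evals[0] * scale))
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return ConfidenceEllipse(center, (major, minor), angle, level)


def ellipse_axis_points(e: ConfidenceEllipse) -> tuple[np.ndarray, np.ndarray]:
    """Major- and minor-axis endpoint pairs, each of shape (2, 2)."""
    u = np.array([np.cos(e.angle), np.sin(e.angle)])
    v = np.array([-np.sin(e.angle), np.cos(e.angle)])
    major = np.stack([e.center + e.semi_axes[0] * u, e.center - e.semi_axes[0] * u])
    minor = np.stack([e.center + e.semi_axes[1] * v, e.center - e.semi_axes[1] * v])
    return major, minor


def ellipse_difference_index(e1: ConfidenceEllipse, e2: ConfidenceEllipse) -> float:
    """Sum of distances between corresponding axis endpoints of two ellipses.

    The four corresponding points are the major- and minor-axis endpoints;
    for each axis, of the two possible orientation pairings the one with
    the smaller summed distance is used (axis orientations are only defined
    up to sign).  The index is a pseudometric: non-negative, symmetric and
    zero exactly for identical ellipses.
    """

    def axis_dist(p: np.ndarray, q: np.ndarray) -> float:
        straight = np.linalg.norm(p[0] - q[0]) + np.linalg.norm(p[1] - q[1])
        flipped = np.linalg.norm(p[0] - q[1]) + np.linalg.norm(p[1] - q[0])
        return min(straight, flipped)

    maj1, min1 = ellipse_axis_points(e1)
    maj2, min2 = ellipse_axis_points(e2)
    return axis_dist(maj1, maj2) + axis_dist(min1, min2)


class NoiseGainEstimator(BaseEstimator):
    """Grid-search estimator of the signal-dependent noise gains (k1, k2).

    scikit-learn style: construct with hyperparameters, call
    :meth:`fit` with observation groups, read fitted attributes.

    Parameters
    ----------
    k_min, k_max, k_step : float
        Coarse search grid for both gains (default 0.05 to 1.20, step 0.05).
    n_sim : int
        Simulated trials per grid cell and condition (default 100).
    level : float
        Confidence-ellipse coverage (default 0.95); the argmin is
        insensitive to the choice as both ellipses use the same level.
    refine : bool
        Run a second pass at ``refine_step`` around the coarse optimum.
    seed : int
        Base seed; one noise stream per (seed, pass, condition) is shared
        across grid cells (common random numbers), so the EDI surface is
        smooth in k and bit-reproducible.
    dt : float
        Forward-integration step for the simulated reaches (s).

    Attributes
    ----------
    k1_, k2_ : float
        Estimated noise gains.
    result_ : GridSearchResult
        Full surface, grids and (if requested) the refinement pass.
    """

    def __init__(
        self,
        k_min: float = 0.05,
        k_max: float = 1.20,
        k_step: float = 0.05,
        n_sim: int = 100,
        level: float = 0.95,
        refine: bool = True,
        refine_step: float = 0.01,
        seed: int = 0,
        dt: float = 1e-3,
        include_interaction: bool = True,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.k_step = k_step
        self.n_sim = n_sim
        self.level = level
        self.refine = refine
        self.refine_step = refine_step
        self.seed = seed
        self.dt = dt
        self.include_interaction = include_interaction

    # -- internals ----------------------------------------------------

    def _grid(self, lo: float, hi: float, step: float) -> np.ndarray:
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)

    def _surface(
        self,
        groups: Sequence[ObservationGroup],
        params: PhysicalParams,
        k1g: np.ndarray,
        k2g: np.ndarray,
        seed_tag: int,
    ) -> np.ndarray:
        """Total EDI for every (k1, k2) cell; one batched rollout per group."""
        n1, n2 = k1g.size, k2g.size
        cells = np.array([(a, b) for a in k1g for b in k2g])  # (n1*n2, 2)
        k_arr = np.repeat(cells, self.n_sim, axis=0)
        total = np.zeros(n1 * n2)
        obs_ellipses = [
            confidence_ellipse(g.endpoints, self.level) for g in groups
        ]
        for gi, (g, e_obs) in enumerate(zip(groups, obs_ellipses)):
            gp = params.with_viscosity(g.B) if g.B is not None else params
            n_pts = 101
            # common random numbers: one stream per (seed, pass, group),
            # shared across grid cells, so the EDI surface is smooth in k
            # and the argmin is not set by cell-to-cell Monte-Carlo jitter
            rng = np.random.default_rng(
                np.random.SeedSequence((self.seed, seed_tag, gi))
            )
            z_group = draw_noise(n_pts, rng, n_trials=self.n_sim)
            z = np.broadcast_to(
                z_group[None], (n1 * n2, self.n_sim, 2, n_pts)
            ).reshape(-1, 2, n_pts)
            end_xy = _rollout_noisy(
                g.desired, gp, k_arr, z, self.dt, self.include_interaction
            )
            sim = end_xy.reshape(n1 * n2, self.n_sim, 2)
            for ci in range(n1 * n2):
                try:
                    e_sim = confidence_ellipse(sim[ci], self.level)
                except ValueError:
                    total[ci] = np.inf
                    continue
                total[ci] += ellipse_difference_index(e_obs, e_sim)
        return total.reshape(n1, n2)

    @staticmethod
    def _argmin(surface: np.ndarray, k1g: np.ndarray, k2g: np.ndarray):
        # ties broken by smallest k1 then k2 (C-order argmin does exactly that)
        i, j = np.unravel_index(np.argmin(surface), surface.shape)
        return float(k1g[i]), float(k2g[j])

    # -- API ----------------------------------------------------------

    def fit(self, groups: Sequence[ObservationGroup], params: PhysicalParams):
        """Estimate (k1, k2) from observed endpoint scatters.

        ``groups`` carries, per (direction, duration-bin) condition, the
        observed endpoints and the trial-averaged desired trajectory;
        ``params`` the subject's physical parameters (per-group viscosity
        overrides taken from ``group.B``).
        """
        usable = []
        for g in groups:
            try:
                confidence_ellipse(g.endpoints, self.level)
            except ValueError as err:
                logger.warning("skipping degenerate group %s: %s", g.label, err)
                continue
            usable.append(g)
        if not usable:
            raise ValueError("all observation groups are degenerate")

        k1g = self._grid(self.k_min, self.k_max, self.k_step)
        k2g = k1g.copy()
        surface = self._surface(usable, params, k1g, k2g, seed_tag=0)
        best = self._argmin(surface, k1g, k2g)
        result = GridSearchResult(
            k1_grid=k1g, k2_grid=k2g, edi_surface=surface,
            best_k=best, n_sim=self.n_sim,
        )
        if self.refine:
            lo1 = max(self.k_min, best[0] - self.k_step)
            hi1 = min(self.k_max, best[0] + self.k_step)
            lo2 = max(self.k_min, best[1] - self.k_step)
            hi2 = min(self.k_max, best[1] + self.k_step)
            f1 = self._grid(lo1, hi1, self.refine_step)
            f2 = self._grid(lo2, hi2, self.refine_step)
            fsurf = self._surface(usable, params, f1, f2, seed_tag=1)
            fbest = self._argmin(fsurf, f1, f2)
            result.refined = GridSearchResult(
                k1_grid=f1, k2_grid=f2, edi_surface=fsurf,
                best_k=fbest, n_sim=self.n_sim,
            )
            best = fbest
        self.result_ = result
        self.k1_, self.k2_ = best
        return self

    @property
    def k_(self) -> NoiseParams:
        return NoiseParams(self.k1_, self.k2_)


def estimate_noise_params(
    groups: Sequence[ObservationGroup],
    params: PhysicalParams,
    **kwargs,
) -> GridSearchResult:
    """Functional wrapper around :class:`NoiseGainEstimator`.

    Returns the coarse :class:`GridSearchResult` (with the refinement pass
    attached when enabled); ``result.best_k`` is the final estimate.
    """
    est = NoiseGainEstimator(**kwargs).fit(groups, params)
    res = est.result_
    if res.refined is not None:
        res = GridSearchResult(
            k1_grid=res.k1_grid, k2_grid=res.k2_grid,
            edi_surface=res.edi_surface, best_k=(est.k1_, est.k2_),
            n_sim=res.n_sim, refined=res.refined,
        )
    return res
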