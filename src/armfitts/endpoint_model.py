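"""Signal-dependent torque noise and its propagation to endpoint error.

The motor command is corrupted by Gaussian noise whose standard deviation
is proportional to the commanded torque:

    tau_noise_i(t) = k_i |tau_i(t)| z_i(t),

with per-joint dimensionless gains ``k_i``.  Propagating this noise through
a first-order expansion of the forward model around the noise-free movement
gives an endpoint error that is exactly inversely proportional to the
movement duration:

    dx(D) = (1/D) sum_i k_i ax_i,   ax_i = int (J^x B^-1)_i |tau_n_i| z_i ds
    W     = sqrt(dx^2 + dy^2) = gamma / D.

Only the viscous row J B^-1 of the propagation matrix enters the position
error; the inertial row J M^-1 governs the velocity error and is exposed for
completeness but unused in W.

Noise convention
----------------
``z_i`` is white in *normalized* time, discretized on a fixed s-grid as
``z_ij = N(0,1) * sqrt(S0_REF / ds)``: Brownian increments whose intensity
is set by the reference step ``S0_REF = 0.004``, the normalized width of
one 500 Hz sample at the centre duration 0.5 s.  Under this convention the
distribution of gamma does not depend on D or on the grid resolution (so
W = gamma/D holds in distribution) and k has the natural per-sample scale
of the measurement rate (k of order 0.2-0.9 produces millimetre-to-
centimetre endpoint scatter on a 15 cm reach).  A real-time white-noise
convention (W ~ D^-3/2) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm_dynamics import PhysicalParams, forward_kinematics, inverse_dynamics, jacobian
from .trajectory import NormalizedTrajectory, TimedTrajectory

__all__ = [
    "S0_REF",
    "NoiseParams",
    "PropagationResult",
    "EndpointCovariance",
    "EndpointSample",
    "draw_noise",
    "sample_torque_noise",
    "linear_endpoint_error",
    "endpoint_covariance",
    "gamma_coefficient",
    "simulate_endpoints_full",
    "fit_rayleigh",
    "model_rmse",
]

#: Reference normalized-time step setting the white-noise intensity.
S0_REF = 0.004


@dataclass
class NoiseParams:
    """Per-joint signal-dependent noise gains (dimensionless, >= 0)."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and np.isfinite(self.k2)):
            raise ValueError("noise gains must be finite")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("noise gains must be >= 0")

    @property
    def k(self) -> np.ndarray:
        return np.array([self.k1, self.k2])


@dataclass
class PropagationResult:
    """One linear-propagation realization at duration ``D``.

    ``alpha_x``/``alpha_y`` are the per-joint propagation integrals (m s);
    ``dx``/``dy`` the endpoint error components; ``gamma = W * D``.
    """

    alpha_x: np.ndarray
    alpha_y: np.ndarray
    dx: float
    dy: float
    gamma: float
    W_model: float
    D: float


@dataclass
class EndpointCovariance:
    """Analytic 2x2 covariance of (dx, dy) at duration ``D``."""

    sigma: np.ndarray
    D: float

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (2, 2) or not np.allclose(s, s.T):
            raise ValueError("sigma must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(s) < -1e-15):
            raise ValueError("sigma must be positive semi-definite")
        self.sigma = s


@dataclass
class EndpointSample:
    """Endpoint error of one simulated (or observed) reach."""

    dx: float
    dy: float
    W: float
    D: float


# ---------------------------------------------------------------------------
# noise draws
# ---------------------------------------------------------------------------

def draw_noise(n_points: int, rng: np.random.Generator, n_trials: int = 1) -> np.ndarray:
    """Scaled white-noise samples z on a uniform s-grid, shape (n_trials, 2, n_points).

    Each sample is N(0,1) * sqrt(S0_REF/ds) with ds the grid spacing, i.e.
    Brownian increments of intensity S0_REF per unit normalized time.
    """
    ds = 1.0 / (n_points - 1)
    z = rng.standard_normal((n_trials, 2, n_points))
    return z * np.sqrt(S0_REF / ds)


def sample_torque_noise(
    tau: np.ndarray,
    k: NoiseParams,
    grid: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Signal-dependent torque noise k_i |tau_i(s_j)| z_ij on a uniform grid.

    ``tau`` has shape (n, 2); the returned noise has the same shape and is
    reproducible for a given seed.
    """
    tau = np.asarray(tau, dtype=float)
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    if grid.ndim != 1 or not np.allclose(steps, steps[0]):
        raise ValueError("grid must be 1-D and uniform")
    if tau.shape != (grid.size, 2):
        raise ValueError("tau must have shape (len(grid), 2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = draw_noise(grid.size, rng)[0]  # (2, n)
    return k.k[None, :] * np.abs(tau) * z.T


# ---------------------------------------------------------------------------
# linear propagation
# ---------------------------------------------------------------------------

def _propagation_integrands(
    ntraj: NormalizedTrajectory, params: PhysicalParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-joint integrands f^x_i(s), f^y_i(s) = (J B^-1)_i |tau_n_i|, shape (n, 2)."""
    if ntraj.tau_n is None:
        raise ValueError("normalized torque not set; apply normalized_torque first")
    if abs(np.linalg.det(params.B)) < 1e-12:
        raise ValueError("viscosity matrix B is singular")
    J = jacobian(ntraj.theta_n, params.L1, params.L2)
    JB = J @ np.linalg.inv(params.B)  # (n, 2, 2): rows (x, y), columns joints
    abs_tau = np.abs(ntraj.tau_n)
    return JB[:, 0, :] * abs_tau, JB[:, 1, :] * abs_tau


def linear_endpoint_error(
    ntraj: NormalizedTrajectory,
    params: PhysicalParams,
    k: NoiseParams,
    D: float,
    z: np.ndarray,
) -> PropagationResult:
    """Endpoint error of one noise realization under linear propagation.

    ``z`` has shape (2, n) on the same s-grid as ``ntraj`` (see
    :func:`draw_noise`).  The propagation integrals use the trapezoid rule.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    fx, fy = _propagation_integrands(ntraj, params)
    z = np.asarray(z, dtype=float)
    s = ntraj.s
    alpha_x = np.trapezoid(fx * z.T, s, axis=0)  # per joint
    alpha_y = np.trapezoid(fy * z.T, s, axis=0)
    dx = float(np.dot(k.k, alpha_x)) / D
    dy = float(np.dot(k.k, alpha_y)) / D
    gamma = float(np.hypot(np.dot(k.k, alpha_x), np.dot(k.k, alpha_y)))
    return PropagationResult(
        alpha_x=alpha_x, alpha_y=alpha_y, dx=dx, dy=dy,
        gamma=gamma, W_model=gamma / D, D=float(D),
    )


def endpoint_covariance(
    ntraj: NormalizedTrajectory,
    params: PhysicalParams,
    k: NoiseParams,
    D: float,
) -> EndpointCovariance:
    """Analytic covariance of (dx, dy) under the linear noise propagation.

    Sigma = (S0_REF / D^2) * sum_i k_i^2 int g_i(s) g_i(s)^T tau_n_i(s)^2 ds
    with g_i the i-th column of [J^x B^-1; J^y B^-1].  The shared z_i
    between the x- and y-integrals induces the dx-dy correlation.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    fx, fy = _propagation_integrands(ntraj, params)
    s = ntraj.s
    k2 = k.k ** 2
    sxx = np.trapezoid(fx * fx, s, axis=0) @ k2
    syy = np.trapezoid(fy * fy, s, axis=0) @ k2
    sxy = np.trapezoid(fx * fy, s, axis=0) @ k2
    sigma = S0_REF / D ** 2 * np.array([[sxx, sxy], [sxy, syy]])
    return EndpointCovariance(sigma=sigma, D=float(D))


def gamma_coefficient(
    ntraj: NormalizedTrajectory,
    params: PhysicalParams,
    k: NoiseParams,
    n_draws: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Mean gamma over seeded noise draws, and the draw set.

    The model endpoint-error curve is W(D) = gamma_bar / D.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fx, fy = _propagation_integrands(ntraj, params)
    z = draw_noise(ntraj.s.size, rng, n_trials=n_draws)  # (n_draws, 2, n)
    ax = np.trapezoid(fx.T[None] * z, ntraj.s, axis=2)  # (n_draws, 2)
    ay = np.trapezoid(fy.T[None] * z, ntraj.s, axis=2)
    gam = np.hypot(ax @ k.k, ay @ k.k)
    return float(gam.mean()), gam


# ---------------------------------------------------------------------------
# full nonlinear simulation
# ---------------------------------------------------------------------------

def _desired_torque_fine(
    desired: TimedTrajectory,
    params: PhysicalParams,
    dt: float,
    include_interaction: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free torque of the desired trajectory on a half-step time grid
    (RK4 needs tau at t, t+dt/2 and t+dt)."""
    from scipy.interpolate import CubicSpline

    tau = inverse_dynamics(
        desired.theta, desired.dtheta, desired.ddtheta, params, include_interaction
    )
    n_steps = int(round(desired.D / dt))
    t_half = np.minimum(np.arange(2 * n_steps + 1) * (dt / 2.0), desired.t[-1])
    tau_half = CubicSpline(desired.t, tau, axis=0)(t_half)
    return t_half, tau_half


def _rollout_noisy(
    desired: TimedTrajectory,
    params: PhysicalParams,
    k_arr: np.ndarray,
    z: np.ndarray,
    dt: float,
    include_interaction: bool,
) -> np.ndarray:
    """Batched RK4 integration of noisy reaches; returns final hand xy.

    ``k_arr`` has shape (n, 2) and ``z`` shape (n, 2, n_s): per-trial noise
    gains and normalized-grid noise (zero-order hold on s-segments, so the
    linear model and the full simulation share the same randomness).
    """
    n = k_arr.shape[0]
    n_s = z.shape[2]
    D = desired.D
    _, tau_half = _desired_torque_fine(desired, params, dt, include_interaction)
    n_steps = (tau_half.shape[0] - 1) // 2

    B = params.B
    L1, S2p, m2 = params.L1, params.S2, params.m2
    I1, I2 = params.I1, params.I2

    theta = np.broadcast_to(desired.theta[0], (n, 2)).copy()
    dtheta = np.broadcast_to(desired.dtheta[0], (n, 2)).copy()

    def accel(th, dth, tau):
        c2 = np.cos(th[:, 1])
        m11 = I1 + I2 + m2 * (L1 ** 2 + 2.0 * L1 * S2p * c2)
        m12 = I2 + m2 * L1 * S2p * c2
        rhs = tau - dth @ B.T
        if include_interaction:
            a = m2 * L1 * S2p * np.sin(th[:, 1])
            d1, d2 = dth[:, 0], dth[:, 1]
            rhs = rhs - np.stack([-a * (2 * d1 * d2 + d2 ** 2), a * d1 ** 2], axis=-1)
        det = m11 * I2 - m12 * m12
        return np.stack(
            [(I2 * rhs[:, 0] - m12 * rhs[:, 1]) / det,
             (m11 * rhs[:, 1] - m12 * rhs[:, 0]) / det],
            axis=-1,
        )

    def noisy_tau(step_half_idx, seg):
        tau_d = tau_half[step_half_idx]  # (2,)
        return tau_d + k_arr * np.abs(tau_d)[None, :] * z[:, :, seg]

    for j in range(n_steps):
        # noise held constant per s-segment; one segment per step midpoint
        seg = min(int((j + 0.5) * dt / D * (n_s - 1)), n_s - 2)
        tau_a = noisy_tau(2 * j, seg)
        tau_m = noisy_tau(2 * j + 1, seg)
        tau_b = noisy_tau(2 * j + 2, seg)
        k1v = accel(theta, dtheta, tau_a)
        k1x = dtheta
        k2v = accel(theta + 0.5 * dt * k1x, dtheta + 0.5 * dt * k1v, tau_m)
        k2x = dtheta + 0.5 * dt * k1v
        k3v = accel(theta + 0.5 * dt * k2x, dtheta + 0.5 * dt * k2v, tau_m)
        k3x = dtheta + 0.5 * dt * k2v
        k4v = accel(theta + dt * k3x, dtheta + dt * k3v, tau_b)
        k4x = dtheta + dt * k3v
        theta = theta + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        dtheta = dtheta + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError("forward integration diverged")

    # Settle correction: after the command ends the residual joint velocity
    # decays under M ddth = -B dth, displacing the hand by a further
    # B^-1 M(theta) dtheta before it comes to rest (theta + B^-1 M dtheta is
    # the conserved quantity of the free decay).  The reported endpoint is
    # that rest position, matching how an observed endpoint is read off
    # once the hand has stopped.
    c2 = np.cos(theta[:, 1])
    m11 = I1 + I2 + m2 * (L1 ** 2 + 2.0 * L1 * S2p * c2)
    m12 = I2 + m2 * L1 * S2p * c2
    mom = np.stack(
        [m11 * dtheta[:, 0] + m12 * dtheta[:, 1],
         m12 * dtheta[:, 0] + I2 * dtheta[:, 1]],
        axis=-1,
    )
    theta_rest = theta + np.linalg.solve(B, mom.T).T
    return forward_kinematics(theta_rest, params.L1, params.L2)


def simulate_endpoints_full(
    desired: TimedTrajectory,
    params: PhysicalParams,
    k: NoiseParams,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    include_interaction: bool = True,
    dt: float = 1e-3,
    n_noise_points: int = 101,
) -> list[EndpointSample]:
    """Monte-Carlo endpoint errors through the full nonlinear dynamics.

    Per trial the desired torque (inverse dynamics of ``desired``) is
    corrupted with signal-dependent noise and integrated forward from the
    true initial state; the endpoint error is the rest position the hand
    settles to once the command ends (integration to t = D plus the
    closed-form viscous-decay displacement) minus the desired endpoint.
    ``include_interaction=False`` drops the Coriolis/centrifugal terms in
    *both* the inverse and forward dynamics.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = draw_noise(n_noise_points, rng, n_trials=n_trials)
    k_arr = np.broadcast_to(k.k, (n_trials, 2))
    end_xy = _rollout_noisy(desired, params, k_arr, z, dt, include_interaction)
    target = forward_kinematics(desired.theta[-1], params.L1, params.L2)
    d = end_xy - target[None, :]
    return [
        EndpointSample(dx=float(d[i, 0]), dy=float(d[i, 1]),
                       W=float(np.hypot(d[i, 0], d[i, 1])), D=desired.D)
        for i in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# distribution fitting and comparison
# ---------------------------------------------------------------------------

def fit_rayleigh(w_samples: np.ndarray) -> float:
    """Maximum-likelihood Rayleigh scale sigma = sqrt(sum w^2 / (2 n)).

    The fitted mean is sigma * sqrt(pi/2).
    """
    w = np.asarray(w_samples, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(w < 0):
        raise ValueError("Rayleigh samples must be non-negative")
    return float(np.sqrt(np.sum(w ** 2) / (2.0 * w.size)))


def model_rmse(observed_means: np.ndarray, gamma_bar: float) -> float:
    """RMSE between observed mean endpoint errors and the model curve.

    ``observed_means`` is an (n, 2) array of (D, W_mean) pairs per duration
    condition; the model mean at each D is gamma_bar / D.
    """
    obs = np.atleast_2d(np.asarray(observed_means, dtype=float))
    if obs.shape[0] < 1 or obs.shape[1] != 2:
        raise ValueError("observed_means must be (n, 2) pairs of (D, W)")
    resid = obs[:, 1] - gamma_bar / obs[:, 0]
    return float(np.sqrt(np.mean(resid ** 2)))
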