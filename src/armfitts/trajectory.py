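"""Trajectory generation, preprocessing and time-normalisation.

Handles the kinematic side of the analysis: generating minimum-jerk
reference reaches, low-pass filtering raw hand positions, detecting
movement onset/offset from the tangential speed, averaging trials, and
re-parameterizing trajectories on normalized time s = t/D in [0, 1] so
their shape becomes duration-free.

On normalized time the equation of motion factorizes as

    tau(D s) = (1/D^2) { M th'' + h1 [th1' th2'] + h2 [th'^2] } + (1/D) B th'

and with the approximation 1/D ~= lambda/D^2 over a bounded duration range
the whole right-hand side collapses to tau(D s) ~= tau_n(s)/D^2, where
``tau_n`` is the duration-free normalized torque computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

from .arm_dynamics import (
    PhysicalParams,
    inertia_matrix,
    interaction_torque,
    inverse_kinematics,
    jacobian,
    jacobian_dot,
)

__all__ = [
    "TimedTrajectory",
    "NormalizedTrajectory",
    "MovementBounds",
    "minimum_jerk_trajectory",
    "minimum_jerk_profile",
    "normalize_time",
    "denormalize_time",
    "fit_lambda",
    "normalized_torque",
    "lowpass_filter",
    "tangential_speed",
    "detect_movement",
    "trial_average",
    "MINJERK_DETECTED_FRACTION",
]


@dataclass
class TimedTrajectory:
    """Joint-space trajectory on a uniform time grid.

    ``theta``, ``dtheta``, ``ddtheta`` have shape (n, 2); ``t`` runs from 0
    to the movement duration ``D`` at sampling rate ``rate``.
    """

    t: np.ndarray
    theta: np.ndarray
    dtheta: np.ndarray
    ddtheta: np.ndarray
    D: float
    rate: float

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("theta", "dtheta", "ddtheta"):
            if getattr(self, name).shape != (n, 2):
                raise ValueError(f"{name} must have shape (len(t), 2)")
        if self.D <= 0:
            raise ValueError("D must be > 0")

    @classmethod
    def from_angles(cls, t: np.ndarray, theta: np.ndarray) -> "TimedTrajectory":
        """Build a trajectory from angles alone, differentiating numerically
        (central differences, one-sided at the ends)."""
        t = np.asarray(t, dtype=float)
        dt = t[1] - t[0]
        dtheta = np.gradient(theta, dt, axis=0)
        ddtheta = np.gradient(dtheta, dt, axis=0)
        return cls(t - t[0], theta, dtheta, ddtheta,
                   D=float(t[-1] - t[0]), rate=1.0 / dt)


@dataclass
class NormalizedTrajectory:
    """Duration-free trajectory on s in [0, 1].

    Derivative fields are with respect to s (chain-rule factors D, D^2
    already applied).  ``tau_n`` is the normalized torque (N m s^2), unset
    until :func:`normalized_torque` is applied.
    """

    s: np.ndarray
    theta_n: np.ndarray
    dtheta_n: np.ndarray
    ddtheta_n: np.ndarray
    tau_n: np.ndarray | None = None
    lambda_used: float | None = None

    def __post_init__(self) -> None:
        if abs(self.s[0]) > 1e-12 or abs(self.s[-1] - 1.0) > 1e-12:
            raise ValueError("normalized grid must span [0, 1]")


class MovementBounds(NamedTuple):
    onset: int
    offset: int
    duration: float
    ballistic: bool


# ---------------------------------------------------------------------------
# reference trajectories
# ---------------------------------------------------------------------------

def minimum_jerk_profile(s: np.ndarray):
    """Fifth-order position profile and its first two s-derivatives."""
    s = np.asarray(s, dtype=float)
    p = 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5
    v = 30 * s ** 2 - 60 * s ** 3 + 30 * s ** 4
    a = 60 * s - 180 * s ** 2 + 120 * s ** 3
    return p, v, a


def minimum_jerk_trajectory(
    start_xy: Sequence[float],
    target_xy: Sequence[float],
    D: float,
    n_samples: int,
    params: PhysicalParams,
) -> TimedTrajectory:
    """Straight-path minimum-jerk reach converted to joint space.

    The hand follows the straight segment from ``start_xy`` to
    ``target_xy`` with the fifth-order polynomial time profile (zero
    boundary velocity and acceleration).  Joint angles come from inverse
    kinematics; joint velocities and accelerations via the Jacobian chain
    rule, which keeps inverse/forward-dynamics round trips at integrator
    precision.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    start = np.asarray(start_xy, dtype=float)
    target = np.asarray(target_xy, dtype=float)
    s = np.linspace(0.0, 1.0, n_samples)
    p, v, a = minimum_jerk_profile(s)
    delta = target - start
    xy = start + p[:, None] * delta
    vxy = (v[:, None] / D) * delta
    axy = (a[:, None] / D ** 2) * delta
    theta = inverse_kinematics(xy, params.L1, params.L2)
    J = jacobian(theta, params.L1, params.L2)
    dtheta = np.linalg.solve(J, vxy[..., None])[..., 0]
    Jd = jacobian_dot(theta, dtheta, params.L1, params.L2)
    rhs = axy - np.einsum("nij,nj->ni", Jd, dtheta)
    ddtheta = np.linalg.solve(J, rhs[..., None])[..., 0]
    return TimedTrajectory(
        t=s * D, theta=theta, dtheta=dtheta, ddtheta=ddtheta,
        D=float(D), rate=(n_samples - 1) / D,
    )


#: Fraction of the true duration recovered by 5%-of-peak threshold detection
#: on a minimum-jerk speed profile: the two roots of 30 s^2 (1-s)^2 =
#: 0.05 * 1.875 are s = (1 -/+ sqrt(1 - 4 sqrt(0.003125)))/2, whose
#: separation is sqrt(1 - 0.2236) = 0.8811.
MINJERK_DETECTED_FRACTION = float(np.sqrt(1.0 - 4.0 * np.sqrt(0.05 * 1.875 / 30.0)))


# ---------------------------------------------------------------------------
# time-normalisation
# ---------------------------------------------------------------------------

def normalize_time(traj: TimedTrajectory) -> NormalizedTrajectory:
    """Map a timed trajectory onto s = t/D with chain-rule derivatives."""
    D = traj.D
    return NormalizedTrajectory(
        s=traj.t / D,
        theta_n=traj.theta.copy(),
        dtheta_n=D * traj.dtheta,
        ddtheta_n=D ** 2 * traj.ddtheta,
    )


def denormalize_time(ntraj: NormalizedTrajectory, D: float) -> TimedTrajectory:
    """Invert :func:`normalize_time` at duration ``D``."""
    if D <= 0:
        raise ValueError("D must be > 0")
    n = ntraj.s.size
    return TimedTrajectory(
        t=ntraj.s * D,
        theta=ntraj.theta_n.copy(),
        dtheta=ntraj.dtheta_n / D,
        ddtheta=ntraj.ddtheta_n / D ** 2,
        D=float(D),
        rate=(n - 1) / D,
    )


def fit_lambda(d_min: float, d_max: float) -> float:
    """Coefficient of the 1/D ~= lambda/D^2 approximation.

    Minimizes the integrated squared residual of the approximation over the
    duration interval; the closed form is the ratio of the integrals of
    D^-3 and D^-4.  A degenerate interval returns the exact match
    lambda = D.
    """
    if not (0 < d_min <= d_max):
        raise ValueError("need 0 < d_min <= d_max")
    if d_min == d_max:
        return float(d_min)
    num = 0.5 * (d_min ** -2 - d_max ** -2)
    den = (d_min ** -3 - d_max ** -3) / 3.0
    return float(num / den)


def normalized_torque(
    ntraj: NormalizedTrajectory,
    params: PhysicalParams,
    lam: float,
    include_interaction: bool = True,
) -> NormalizedTrajectory:
    """Duration-free torque tau_n(s); returns a copy with ``tau_n`` set.

    tau_n = M th'' + h1 [th1' th2'] + h2 [th'^2] + lambda B th', so that
    tau(D s) ~= tau_n(s)/D^2, exactly when B = 0 or D = lambda.
    """
    th, dth, ddth = ntraj.theta_n, ntraj.dtheta_n, ntraj.ddtheta_n
    M = inertia_matrix(th[..., 1], params)
    tau = np.einsum("...ij,...j->...i", M, ddth)
    if include_interaction:
        tau += interaction_torque(th[..., 1], dth, params)
    tau += lam * (dth @ params.B.T)
    return replace(ntraj, tau_n=tau, lambda_used=float(lam))


# ---------------------------------------------------------------------------
# preprocessing of measured series
# ---------------------------------------------------------------------------

def lowpass_filter(
    series: np.ndarray, rate: float, fc: float = 10.0, order: int = 3
) -> np.ndarray:
    """Zero phase-lag Butterworth low-pass (forward-backward) along axis 0.

    The forward-backward pass squares the magnitude response, so the
    effective gain at the cut-off is 0.5.
    """
    if rate <= 2.0 * fc:
        raise ValueError("sampling rate must exceed twice the cut-off")
    series = np.asarray(series, dtype=float)
    b, a = signal.butter(order, fc, fs=rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise ValueError("series too short for zero-phase filtering")
    return signal.filtfilt(b, a, series, axis=0)


def tangential_speed(xy: np.ndarray, rate: float) -> np.ndarray:
    """Hand speed |dx/dt, dy/dt| by central differences."""
    v = np.gradient(np.asarray(xy, dtype=float), 1.0 / rate, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def detect_movement(
    speed: np.ndarray, rate: float, frac: float = 0.05
) -> MovementBounds:
    """Threshold-based onset/offset detection on a tangential-speed series.

    Onset is the first sample exceeding ``frac`` of the peak speed, offset
    the last sample above it.  The movement is flagged ballistic when the
    above-threshold segment contains exactly one local speed maximum;
    maxima are counted with a prominence of ``frac`` of the peak so that
    residual measurement noise on an otherwise single-peaked profile does
    not register as extra peaks.
    """
    speed = np.asarray(speed, dtype=float)
    peak = speed.max()
    if peak <= 0:
        raise ValueError("no movement: speed series has no positive peak")
    thr = frac * peak
    above = np.nonzero(speed > thr)[0]
    onset, offset = int(above[0]), int(above[-1])
    seg = speed[onset : offset + 1]
    peaks, _ = signal.find_peaks(seg, height=thr, prominence=frac * peak)
    n_peaks = max(1, peaks.size)  # the global peak may sit at a segment edge
    return MovementBounds(
        onset=onset,
        offset=offset,
        duration=(offset - onset) / rate,
        ballistic=n_peaks == 1,
    )


def trial_average(trials: Sequence[TimedTrajectory]) -> TimedTrajectory:
    """Average joint trajectories across trials at the mean duration.

    Each trial is mapped to normalized time, resampled onto a common grid
    of length round(mean(D) * rate) + 1, averaged pointwise in angle space,
    and the derivatives recomputed from the averaged angles.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    rate = trials[0].rate
    d_mean = float(np.mean([tr.D for tr in trials]))
    n = int(round(d_mean * rate)) + 1
    s_common = np.linspace(0.0, 1.0, n)
    acc = np.zeros((n, 2))
    for tr in trials:
        s = tr.t / tr.D
        for j in range(2):
            acc[:, j] += np.interp(s_common, s, tr.theta[:, j])
    acc /= len(trials)
    return TimedTrajectory.from_angles(s_common * d_mean, acc)
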