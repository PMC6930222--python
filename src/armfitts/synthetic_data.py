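"""Synthetic centre-out reaching experiments with known ground truth.

Emulates the structure of a temporally constrained centre-out reaching
study: 15 cm reaches in four directions (right 0, front 90, left 180,
back 270 degrees) from a 45/100-degree start posture, four target
duration bins from 0.30 to 0.70 s, and 20 successful trials per
(direction, bin) cell — 320 successes in all.  Each trial is a full
forward-dynamics simulation under signal-dependent torque noise with known
gains ``k_true``, recorded as a 500 Hz hand-position series with additive
Gaussian measurement noise, and judged by the same duration-window and
single-peak (ballistic) criteria the analysis pipeline applies.  Failed
attempts are kept (flagged) so rejection code paths are exercisable.

The generator's purpose is parameter-recovery testing: the bundled ground
truth carries the noise gains, desired trajectories and true endpoint
errors that the analysis is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .arm_dynamics import (
    AIR_SLED_MASS,
    PhysicalParams,
    REFERENCE_ARM_LENGTHS,
    TorqueSeries,
    default_viscosity,
    estimate_physical_params,
    forward_dynamics,
    forward_kinematics,
    inverse_dynamics,
)
from .endpoint_model import NoiseParams, draw_noise
from .trajectory import (
    MINJERK_DETECTED_FRACTION,
    TimedTrajectory,
    detect_movement,
    lowpass_filter,
    minimum_jerk_trajectory,
    tangential_speed,
)

__all__ = [
    "DIRECTION_ANGLES",
    "ExperimentConfig",
    "TrialRecord",
    "GroundTruth",
    "generate_subject",
    "generate_dataset",
]

#: Target direction labels and their angles (degrees) from the start point.
DIRECTION_ANGLES = {"right": 0.0, "front": 90.0, "left": 180.0, "back": 270.0}


@dataclass
class ExperimentConfig:
    """Study-design constants of the synthetic experiment.

    Defaults are the reference task: four directions, 0.15 m distance,
    duration bins 0.30-0.40/0.40-0.50/0.50-0.60/0.60-0.70 s, 20 successes
    per cell at 500 Hz, start posture (45, 100) degrees.
    ``measurement_noise_sd`` models the optical digitizer (0.2 mm).
    """

    directions: tuple = ("right", "front", "left", "back")
    distance: float = 0.15
    duration_bins: tuple = ((0.30, 0.40), (0.40, 0.50), (0.50, 0.60), (0.60, 0.70))
    trials_per_cell: int = 20
    rate: float = 500.0
    start_posture_deg: tuple = (45.0, 100.0)
    k_true: NoiseParams = field(default_factory=lambda: NoiseParams(0.5, 0.7))
    measurement_noise_sd: float = 2e-4
    pre_hold: float = 0.2  # recorded rest before the start cue, s
    tail: float = 1.2  # recorded settle period after the movement, s
    seed: int = 0

    def __post_init__(self) -> None:
        bins = list(self.duration_bins)
        if any(b[0] >= b[1] for b in bins):
            raise ValueError("duration bins must be increasing intervals")
        if any(bins[i][1] > bins[i + 1][0] + 1e-12 for i in range(len(bins) - 1)):
            raise ValueError("duration bins must be non-overlapping and sorted")
        if self.trials_per_cell < 1 or self.rate <= 0:
            raise ValueError("counts and rate must be positive")
        unknown = set(self.directions) - set(DIRECTION_ANGLES)
        if unknown:
            raise ValueError(f"unknown directions: {sorted(unknown)}")


@dataclass
class TrialRecord:
    """One synthetic reach: measured series plus success bookkeeping.

    ``D`` is the detected movement duration of the measured series; ``W``
    the true endpoint error (settled hand position vs target, before
    measurement noise).
    """

    trial_id: int
    direction: str
    bin: tuple[float, float]
    D: float
    t: np.ndarray
    xy: np.ndarray
    success: bool
    W: float


@dataclass
class GroundTruth:
    """Generating quantities retained for recovery tests."""

    k_true: NoiseParams
    subject: PhysicalParams
    start_xy: np.ndarray
    targets: dict
    desired: dict  # (direction, bin) -> list of commanded TimedTrajectory
    true_errors: dict  # (direction, bin) -> (n, 2) settled endpoint errors
    config: ExperimentConfig


def generate_subject(seed: int = 0) -> PhysicalParams:
    """Draw a subject's arm from the reference length distribution.

    Link lengths are normal around the reference means (SDs from the same
    table), truncated at 3 SD; the remaining parameters follow from the
    anthropometric proportionality fit with the air-sled mass attached.
    """
    rng = np.random.default_rng(seed)

    def trunc_normal(mean: float, sd: float) -> float:
        while True:
            v = rng.normal(mean, sd)
            if abs(v - mean) <= 3 * sd:
                return v

    L1 = trunc_normal(*REFERENCE_ARM_LENGTHS["L1"])
    L2 = trunc_normal(*REFERENCE_ARM_LENGTHS["L2"])
    return estimate_physical_params(L1, L2, attached_mass=AIR_SLED_MASS)


def _simulate_trial(
    desired: TimedTrajectory,
    params: PhysicalParams,
    k: NoiseParams,
    rng: np.random.Generator,
    config: ExperimentConfig,
    dt: float = 1e-3,
    n_noise_points: int = 101,
):
    """Integrate one noisy reach plus settle tail; returns (t, xy, true_xy_end).

    The commanded torque is the inverse dynamics of ``desired`` corrupted
    by signal-dependent noise (held constant per normalized-time segment);
    after the command ends the torque is zero and the arm settles.
    """
    D = desired.D
    tau_des = inverse_dynamics(desired.theta, desired.dtheta, desired.ddtheta, params)
    n_mov = int(round(D / dt))
    # half-step torque grid: RK4 then evaluates tau only at exact nodes
    t_fine = np.minimum(np.arange(2 * n_mov + 1) * (dt / 2.0), D)
    tau_fine = CubicSpline(desired.t, tau_des, axis=0)(t_fine)
    z = draw_noise(n_noise_points, rng, 1)[0]  # (2, n_pts)
    seg = np.minimum(
        (t_fine / D * (n_noise_points - 1)).astype(int), n_noise_points - 2
    )
    tau_fine += k.k[None, :] * np.abs(tau_fine) * z[:, seg].T
    t_mov, theta, dtheta = forward_dynamics(
        TorqueSeries(t_fine, tau_fine), desired.theta[0], desired.dtheta[0],
        params, dt=dt,
    )
    # torque-free settle tail at the (coarser) recording step
    dt_rec = 1.0 / config.rate
    n_tail = int(round(config.tail * config.rate))
    t_tail, theta_t, dtheta_t = forward_dynamics(
        lambda t: np.zeros(2), theta[-1], dtheta[-1], params,
        dt=dt_rec, t_end=n_tail * dt_rec,
    )
    # true endpoint: rest position after the residual velocity fully decays
    # (theta + B^-1 M dtheta is conserved under the free viscous decay)
    from .arm_dynamics import inertia_matrix

    M_end = inertia_matrix(theta_t[-1, 1], params)
    theta_rest = theta_t[-1] + np.linalg.solve(params.B, M_end @ dtheta_t[-1])
    xy_rest = forward_kinematics(theta_rest, params.L1, params.L2)
    # recorded series at the recording rate
    step = int(round(dt_rec / dt))
    theta_rec = np.vstack([theta[::step], theta_t[1:]])
    t_rec = np.arange(theta_rec.shape[0]) * dt_rec
    xy = forward_kinematics(theta_rec, params.L1, params.L2)
    return t_rec, xy, xy_rest


def generate_dataset(
    config: ExperimentConfig, subject: PhysicalParams
) -> tuple[list[TrialRecord], GroundTruth]:
    """Run the synthetic experiment until every cell has its successes.

    Per (direction, bin) cell, attempts draw a target detected-duration
    uniformly in the bin, command the corresponding minimum-jerk reach
    (correcting for the 5%-threshold shortening of detected durations),
    simulate it under the true noise gains, add measurement noise, and
    apply the success criteria (detected duration inside the bin, single
    speed peak).  Attempts continue until ``trials_per_cell`` successes;
    a success rate below 1% raises.
    """
    theta0 = np.deg2rad(config.start_posture_deg)
    start_xy = forward_kinematics(theta0, subject.L1, subject.L2)
    targets = {
        d: start_xy + config.distance * np.array(
            [np.cos(np.deg2rad(DIRECTION_ANGLES[d])),
             np.sin(np.deg2rad(DIRECTION_ANGLES[d]))]
        )
        for d in config.directions
    }
    ss = np.random.SeedSequence(config.seed)
    cell_seeds = ss.spawn(len(config.directions) * len(config.duration_bins))

    trials: list[TrialRecord] = []
    desired_all: dict = {}
    true_err: dict = {}
    trial_id = 0
    max_attempts = int(np.ceil(config.trials_per_cell / 0.01))

    for ci, (direction, dbin) in enumerate(
        (d, b) for d in config.directions for b in config.duration_bins
    ):
        rng = np.random.default_rng(cell_seeds[ci])
        params = subject.with_viscosity(default_viscosity(direction))
        n_success = 0
        attempts = 0
        desired_all[(direction, dbin)] = []
        errs = []
        while n_success < config.trials_per_cell:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"cell {direction}/{dbin}: success rate below 1% — "
                    "configuration infeasible"
                )
            # aim inside the window: subjects target the bin interior, so
            # draw from the central half; duration jitter spreads realized
            # durations over the bin and edge-rejection stays rare (full-bin
            # targets make the window check selectively discard large-error
            # trials, distorting the endpoint distributions)
            w = dbin[1] - dbin[0]
            d_target = rng.uniform(dbin[0] + w / 4.0, dbin[1] - w / 4.0)
            # quantize to the recording period so the integration grid
            # covers the commanded movement exactly
            d_cmd = (
                round(d_target / MINJERK_DETECTED_FRACTION * config.rate)
                / config.rate
            )
            n_samp = int(round(d_cmd * config.rate)) + 1
            desired = minimum_jerk_trajectory(
                start_xy, targets[direction], d_cmd, n_samp, params
            )
            t, xy_true, xy_end = _simulate_trial(desired, params, config.k_true,
                                                 rng, config)
            w_true = float(np.linalg.norm(xy_end - targets[direction]))
            # prepend the pre-cue hold and add measurement noise
            n_pre = int(round(config.pre_hold * config.rate))
            t_rec = np.arange(t.size + n_pre) / config.rate
            xy_rec = np.vstack([np.tile(xy_true[0], (n_pre, 1)), xy_true])
            if config.measurement_noise_sd > 0:
                xy_rec = xy_rec + rng.normal(
                    0.0, config.measurement_noise_sd, xy_rec.shape
                )
            filt = lowpass_filter(xy_rec, config.rate)
            speed = tangential_speed(filt, config.rate)
            try:
                bounds = detect_movement(speed, config.rate)
                ok = (dbin[0] <= bounds.duration <= dbin[1]) and bounds.ballistic
                d_obs = bounds.duration
            except ValueError:
                ok, d_obs = False, np.nan
            if ok:
                n_success += 1
                desired_all[(direction, dbin)].append(desired)
                errs.append(xy_end - targets[direction])
            trials.append(
                TrialRecord(
                    trial_id=trial_id, direction=direction, bin=dbin,
                    D=float(d_obs), t=t_rec, xy=xy_rec, success=bool(ok),
                    W=w_true,
                )
            )
            trial_id += 1
        true_err[(direction, dbin)] = np.array(errs)

    truth = GroundTruth(
        k_true=config.k_true, subject=subject, start_xy=start_xy,
        targets=targets, desired=desired_all, true_errors=true_err,
        config=config,
    )
    return trials, truth
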