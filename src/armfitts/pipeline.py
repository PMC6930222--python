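"""End-to-end analysis: raw trials to a model-vs-observed report.

The chain mirrors how a temporally constrained reaching experiment is
analysed: low-pass filter the 500 Hz hand paths, detect movement bounds
from the tangential speed, compute per-trial observed endpoint errors,
convert to joint space by inverse kinematics, average trials per
(direction, duration-bin) condition, estimate the arm's physical
parameters from the link lengths, estimate the noise gains (k1, k2) by
EDI grid search, and compare the resulting model endpoint-error curve
W = gamma/D with the observed means — including the Fitts'-law reading of
both.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arm_dynamics import (
    AIR_SLED_MASS,
    PhysicalParams,
    default_viscosity,
    estimate_physical_params,
    forward_kinematics,
    inverse_kinematics,
)
from .endpoint_model import NoiseParams, fit_rayleigh, gamma_coefficient, model_rmse
from .fitts_law import choose_c, fit_fitts_regression, model_fitts_coeffs
from .noise_estimation import NoiseGainEstimator, ObservationGroup
from .synthetic_data import DIRECTION_ANGLES, TrialRecord
from .trajectory import (
    TimedTrajectory,
    detect_movement,
    fit_lambda,
    lowpass_filter,
    normalize_time,
    normalized_torque,
    tangential_speed,
    trial_average,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "export_report",
    "load_report",
    "write_trial_csv",
    "read_trial_csv",
]


@dataclass
class AnalysisConfig:
    """Analysis-stage settings; defaults match the reference task."""

    distance: float = 0.15
    directions: tuple = ("right", "front", "left", "back")
    duration_bins: tuple = ((0.30, 0.40), (0.40, 0.50), (0.50, 0.60), (0.60, 0.70))
    rate: float = 500.0
    start_posture_deg: tuple = (45.0, 100.0)
    attached_mass: float = AIR_SLED_MASS
    min_trials_per_cell: int = 3
    # noise-gain grid search
    k_min: float = 0.05
    k_max: float = 1.20
    k_step: float = 0.05
    n_sim: int = 100
    refine: bool = True
    refine_step: float = 0.01
    ellipse_level: float = 0.95
    # model curve and Fitts'-law reading
    n_gamma_draws: int = 100
    c_rule: str = "harmonic"
    c_override: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("directions", "start_posture_deg"):
            if key in data:
                data[key] = tuple(data[key])
        if "duration_bins" in data:
            data["duration_bins"] = tuple(tuple(b) for b in data["duration_bins"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)


@dataclass
class AnalysisReport:
    """Serializable analysis output, per direction plus provenance."""

    k_hat: dict
    per_direction: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_hat": _plain(self.k_hat),
            "per_direction": _plain(self.per_direction),
            "provenance": _plain(self.provenance),
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON/YAML round trips."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# trial CSV I/O
# ---------------------------------------------------------------------------

def write_trial_csv(trials: list[TrialRecord], path) -> None:
    """Long-form trial CSV: trial_id, direction, success, t, x, y."""
    frames = [
        pd.DataFrame(
            {
                "trial_id": tr.trial_id,
                "direction": tr.direction,
                "success": tr.success,
                "t": tr.t,
                "x": tr.xy[:, 0],
                "y": tr.xy[:, 1],
            }
        )
        for tr in trials
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "direction", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    if "success" not in df.columns:
        df["success"] = True
    return df


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class _Preprocessed:
    direction: str
    bin: tuple | None
    D: float
    endpoint: np.ndarray  # filtered hand position at movement offset
    W_obs: float
    joint_traj: TimedTrajectory


def _preprocess_trial(
    t: np.ndarray,
    xy: np.ndarray,
    direction: str,
    params: PhysicalParams,
    cfg: AnalysisConfig,
    target: np.ndarray,
) -> _Preprocessed | None:
    xy_f = lowpass_filter(xy, cfg.rate)
    speed = tangential_speed(xy_f, cfg.rate)
    try:
        bounds = detect_movement(speed, cfg.rate)
    except ValueError:
        return None
    if not bounds.ballistic:
        return None
    dbin = next(
        (b for b in cfg.duration_bins if b[0] <= bounds.duration <= b[1]), None
    )
    seg = xy_f[bounds.onset : bounds.offset + 1]
    theta = inverse_kinematics(seg, params.L1, params.L2)
    traj = TimedTrajectory.from_angles(
        np.arange(seg.shape[0]) / cfg.rate, theta
    )
    # endpoint: settled rest position after the movement.  Without online
    # correction the arm drifts measurably after the speed drops below the
    # detection threshold (slow viscous mode), so the endpoint is read once
    # it has settled — averaged over the final samples to suppress
    # measurement noise — rather than at the offset sample itself.
    n_settle = max(1, int(round(0.04 * cfg.rate)))
    endpoint = xy_f[-n_settle:].mean(axis=0)
    return _Preprocessed(
        direction=direction,
        bin=dbin,
        D=bounds.duration,
        endpoint=endpoint,
        W_obs=float(np.linalg.norm(endpoint - target)),
        joint_traj=traj,
    )


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def preprocess_groups(
    trial_data,
    arm_lengths: tuple[float, float],
    cfg: AnalysisConfig,
):
    """Filter/detect/IK all successful trials and bin them per condition.

    Returns ``(params, cells, missing)``: the estimated arm parameters, a
    dict mapping (direction, bin) to preprocessed trials, and the list of
    cells with too few trials.
    """
    if isinstance(trial_data, (str, Path)):
        trial_data = read_trial_csv(trial_data)
    if isinstance(trial_data, pd.DataFrame):
        iterator = [
            (
                grp["t"].to_numpy(),
                grp[["x", "y"]].to_numpy(),
                str(grp["direction"].iloc[0]),
                bool(grp["success"].iloc[0]),
            )
            for _, grp in trial_data.groupby("trial_id", sort=True)
        ]
    else:  # list of TrialRecord
        iterator = [(tr.t, tr.xy, tr.direction, tr.success) for tr in trial_data]

    params = estimate_physical_params(
        arm_lengths[0], arm_lengths[1], attached_mass=cfg.attached_mass
    )
    theta0 = np.deg2rad(cfg.start_posture_deg)
    start_xy = forward_kinematics(theta0, params.L1, params.L2)
    targets = {
        d: start_xy
        + cfg.distance
        * np.array(
            [np.cos(np.deg2rad(DIRECTION_ANGLES[d])),
             np.sin(np.deg2rad(DIRECTION_ANGLES[d]))]
        )
        for d in cfg.directions
    }

    cells: dict = {
        (d, b): [] for d in cfg.directions for b in cfg.duration_bins
    }
    for t, xy, direction, success in iterator:
        if not success or direction not in targets:
            continue
        prep = _preprocess_trial(
            np.asarray(t, float), np.asarray(xy, float), direction, params,
            cfg, targets[direction],
        )
        if prep is None or prep.bin is None:
            continue
        cells[(direction, prep.bin)].append(prep)

    missing = [
        {"direction": d, "bin": list(b)}
        for (d, b), preps in cells.items()
        if len(preps) < cfg.min_trials_per_cell
    ]
    for cell in missing:
        logger.warning("cell %s/%s marked missing (too few trials)",
                       cell["direction"], cell["bin"])
    return params, cells, missing


def build_observation_groups(cells, cfg: AnalysisConfig):
    """Observation groups (endpoints + trial-average desired) per usable cell."""
    groups = []
    for (d, b), preps in cells.items():
        if len(preps) < cfg.min_trials_per_cell:
            continue
        groups.append(
            ObservationGroup(
                endpoints=np.array([p.endpoint for p in preps]),
                desired=trial_average([p.joint_traj for p in preps]),
                direction=d,
                label=f"{d}/{b[0]:.2f}-{b[1]:.2f}",
                B=default_viscosity(d),
            )
        )
    return groups


def run_analysis(
    trial_data,
    arm_lengths: tuple[float, float],
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full chain on trial data.

    Parameters
    ----------
    trial_data : path, DataFrame or list of TrialRecord
        500 Hz hand-position series per trial (shoulder-origin metres).
        Only successful trials enter the analysis.
    arm_lengths : (L1, L2)
        The subject's upper-arm and forearm lengths (m).
    config : AnalysisConfig
        Task constants and estimation settings.

    Returns
    -------
    AnalysisReport
        Per-direction gamma, RMSE, Rayleigh scale, Fitts'-law fits and the
        model's Fitts'-law coefficients; deterministic for a fixed config.
    """
    cfg = config or AnalysisConfig()
    params, cells, missing = preprocess_groups(trial_data, arm_lengths, cfg)
    groups = build_observation_groups(cells, cfg)
    if not groups:
        raise ValueError("no usable (direction, bin) cells in the data")
    estimator = NoiseGainEstimator(
        k_min=cfg.k_min, k_max=cfg.k_max, k_step=cfg.k_step, n_sim=cfg.n_sim,
        level=cfg.ellipse_level, refine=cfg.refine,
        refine_step=cfg.refine_step, seed=cfg.seed,
    )
    estimator.fit(groups, params)
    k_hat = NoiseParams(estimator.k1_, estimator.k2_)

    lam = fit_lambda(cfg.duration_bins[0][0], cfg.duration_bins[-1][1])

    # --- per-direction model curve and Fitts'-law reading ---------------
    per_direction = {}
    for di, d in enumerate(cfg.directions):
        preps = [p for b in cfg.duration_bins for p in cells[(d, b)]]
        if not preps:
            per_direction[d] = {"missing": True}
            continue
        pdir = params.with_viscosity(default_viscosity(d))
        pooled = trial_average([p.joint_traj for p in preps])
        ntraj = normalized_torque(normalize_time(pooled), pdir, lam)
        gamma_bar, _ = gamma_coefficient(
            ntraj, pdir, k_hat, n_draws=cfg.n_gamma_draws,
            seed=np.random.default_rng(
                np.random.SeedSequence((cfg.seed, 1000 + di))
            ),
        )
        bin_rows = []
        for b in cfg.duration_bins:
            preps_b = cells[(d, b)]
            if len(preps_b) < cfg.min_trials_per_cell:
                bin_rows.append({"bin": list(b), "D_mean": None, "W_mean": None,
                                 "W_model": None})
                continue
            d_mean = float(np.mean([p.D for p in preps_b]))
            w_mean = float(np.mean([p.W_obs for p in preps_b]))
            bin_rows.append({
                "bin": list(b), "D_mean": d_mean, "W_mean": w_mean,
                "W_model": gamma_bar / d_mean, "n_trials": len(preps_b),
            })
        obs_pairs = np.array(
            [[r["D_mean"], r["W_mean"]] for r in bin_rows if r["D_mean"]]
        )
        rmse = model_rmse(obs_pairs, gamma_bar) if obs_pairs.size else None
        w_all = np.array([p.W_obs for p in preps])
        rayleigh_sigma = fit_rayleigh(w_all)
        fit = (
            fit_fitts_regression(obs_pairs, A=cfg.distance)
            if obs_pairs.shape[0] >= 2 else None
        )
        c = cfg.c_override or choose_c(obs_pairs[:, 1], rule=cfg.c_rule)
        lin = model_fitts_coeffs(gamma_bar, c)
        per_direction[d] = {
            "missing": False,
            "gamma_bar": gamma_bar,
            "lambda": lam,
            "rmse": rmse,
            "rayleigh_sigma": rayleigh_sigma,
            "bins": bin_rows,
            "fitts": asdict(fit) if fit else None,
            "linearization": asdict(lin),
        }

    cfg_blob = json.dumps(_plain(asdict(cfg)), sort_keys=True)
    report = AnalysisReport(
        k_hat={"k1": float(k_hat.k1), "k2": float(k_hat.k2),
               "grid_step": cfg.refine_step if cfg.refine else cfg.k_step},
        per_direction=per_direction,
        provenance={
            "config": json.loads(cfg_blob),
            "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
            "seed": cfg.seed,
            "missing_cells": missing,
        },
    )
    return report


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def export_report(report: AnalysisReport, path, format: str = "json") -> None:
    """Write the report; JSON is canonical and lossless, CSV flattens the
    per-(direction, bin) comparison table (missing cells as empty fields)."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    elif format == "csv":
        rows = []
        for d, block in report.per_direction.items():
            if block.get("missing"):
                continue
            for r in block["bins"]:
                rows.append({
                    "direction": d,
                    "bin_low": r["bin"][0], "bin_high": r["bin"][1],
                    "D_mean": r["D_mean"], "W_mean": r["W_mean"],
                    "W_model": r["W_model"],
                    "gamma_bar": block["gamma_bar"], "rmse": block["rmse"],
                })
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")


def load_report(path) -> AnalysisReport:
    with open(path) as fh:
        data = json.load(fh)
    return AnalysisReport(
        k_hat=data["k_hat"],
        per_direction=data["per_direction"],
        provenance=data["provenance"],
    )
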