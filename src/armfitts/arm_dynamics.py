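"""Planar two-link arm kinematics and dynamics.

The arm is modelled as a two-link planar manipulator moving in the
horizontal plane (no gravity term): link 1 is the upper arm rotating about
the shoulder, link 2 the forearm rotating about the elbow.  The shoulder
angle ``theta1`` is measured from the +x axis, the elbow angle ``theta2``
relative to the upper-arm direction; both are in radians internally.

The equation of motion is

    tau = M(theta) ddtheta + h1(theta) [dtheta1*dtheta2]
          + h2(theta) [dtheta^2] + B dtheta

with the inertia matrix (moments of inertia taken about the joints)

    M11 = I1 + I2 + m2 (L1^2 + 2 L1 S2 cos theta2)
    M12 = M21 = I2 + m2 L1 S2 cos theta2
    M22 = I2

Coriolis and centrifugal terms derive from the same Lagrangian with
coefficient ``a = m2 L1 S2 sin theta2``:

    tau1 += -2 a dtheta1 dtheta2 - a dtheta2^2
    tau2 +=  a dtheta1^2

``B`` is a symmetric 2x2 joint viscosity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "PhysicalParams",
    "TorqueSeries",
    "forward_kinematics",
    "inverse_kinematics",
    "jacobian",
    "jacobian_dot",
    "inertia_matrix",
    "interaction_torque",
    "inverse_dynamics",
    "forward_dynamics",
    "estimate_physical_params",
    "default_viscosity",
    "fit_anthropometric_coefficients",
    "DEFAULT_ANTHRO_COEFFS",
    "REFERENCE_ARM_TABLE",
    "AIR_SLED_MASS",
]

#: Mass (kg) of the air-sled and tape attached to the forearm during the
#: reference recordings; added to the estimated forearm mass by default.
AIR_SLED_MASS = 0.740

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class PhysicalParams:
    """Physical parameters of a two-link planar arm.

    Attributes
    ----------
    L1, L2 : float
        Upper-arm and forearm link lengths (m).
    S1, S2 : float
        Joint-to-centre-of-mass distances (m).
    m1, m2 : float
        Link masses (kg); ``m2`` may include an attached mass (air-sled).
    I1, I2 : float
        Moments of inertia about the proximal joint (kg m^2).
    B : ndarray, shape (2, 2)
        Symmetric joint viscosity matrix (kg m^2 / s).
    """

    L1: float
    L2: float
    S1: float
    S2: float
    m1: float
    m2: float
    I1: float
    I2: float
    B: np.ndarray = field(default_factory=lambda: default_viscosity("front"))

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "S1", "S2", "m1", "m2", "I1", "I2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (2, 2):
            raise ValueError("B must be a 2x2 matrix")
        if not np.allclose(self.B, self.B.T):
            raise ValueError("B must be symmetric")

    def with_viscosity(self, B: np.ndarray) -> "PhysicalParams":
        """Return a copy with a different viscosity matrix."""
        return replace(self, B=np.asarray(B, dtype=float))

    def to_dict(self) -> dict:
        return {
            "L1": self.L1, "L2": self.L2, "S1": self.S1, "S2": self.S2,
            "m1": self.m1, "m2": self.m2, "I1": self.I1, "I2": self.I2,
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalParams":
        d = dict(d)
        d["B"] = np.asarray(d["B"], dtype=float)
        return cls(**d)


@dataclass
class TorqueSeries:
    """Per-joint torque samples on a strictly increasing time grid."""

    t: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        if self.tau.shape != (self.t.size, 2):
            raise ValueError("tau must have shape (len(t), 2)")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


def _check_lengths(L1: float, L2: float) -> None:
    if L1 <= 0 or L2 <= 0 or not (np.isfinite(L1) and np.isfinite(L2)):
        raise ValueError("link lengths must be finite and > 0")


def forward_kinematics(theta: np.ndarray, L1: float, L2: float) -> np.ndarray:
    """Hand position (x, y) in the shoulder-origin frame.

    ``theta`` has shape (..., 2); the result has the same leading shape.
    """
    _check_lengths(L1, L2)
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("joint angles must be finite")
    t1 = theta[..., 0]
    t12 = t1 + theta[..., 1]
    return np.stack(
        [L1 * np.cos(t1) + L2 * np.cos(t12), L1 * np.sin(t1) + L2 * np.sin(t12)],
        axis=-1,
    )


def inverse_kinematics(
    xy: np.ndarray, L1: float, L2: float, elbow_positive: bool = True
) -> np.ndarray:
    """Joint angles reaching ``xy``; raises if outside the open workspace.

    The default branch has ``theta2 > 0`` (elbow flexed the way a right arm
    rests at the 45/100-degree start posture).
    """
    _check_lengths(L1, L2)
    xy = np.asarray(xy, dtype=float)
    r2 = xy[..., 0] ** 2 + xy[..., 1] ** 2
    c2 = (r2 - L1 ** 2 - L2 ** 2) / (2.0 * L1 * L2)
    if np.any(np.abs(c2) >= 1.0):
        raise ValueError(
            "hand position outside the open workspace "
            f"(|L1-L2| < r < L1+L2): r={np.sqrt(np.max(r2)):.4f}"
        )
    t2 = np.arccos(c2)
    if not elbow_positive:
        t2 = -t2
    t1 = np.arctan2(xy[..., 1], xy[..., 0]) - np.arctan2(
        L2 * np.sin(t2), L1 + L2 * np.cos(t2)
    )
    return np.stack([t1, t2], axis=-1)


def jacobian(theta: np.ndarray, L1: float, L2: float) -> np.ndarray:
    """Hand Jacobian d(x,y)/d(theta1,theta2), shape (..., 2, 2)."""
    _check_lengths(L1, L2)
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("joint angles must be finite")
    t1 = theta[..., 0]
    t12 = t1 + theta[..., 1]
    s1, c1 = np.sin(t1), np.cos(t1)
    s12, c12 = np.sin(t12), np.cos(t12)
    J = np.empty(theta.shape[:-1] + (2, 2))
    J[..., 0, 0] = -L1 * s1 - L2 * s12
    J[..., 0, 1] = -L2 * s12
    J[..., 1, 0] = L1 * c1 + L2 * c12
    J[..., 1, 1] = L2 * c12
    return J


def jacobian_dot(
    theta: np.ndarray, dtheta: np.ndarray, L1: float, L2: float
) -> np.ndarray:
    """Time derivative of the hand Jacobian along (theta, dtheta)."""
    theta = np.asarray(theta, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    t1 = theta[..., 0]
    t12 = t1 + theta[..., 1]
    d1 = dtheta[..., 0]
    d12 = d1 + dtheta[..., 1]
    s1, c1 = np.sin(t1), np.cos(t1)
    s12, c12 = np.sin(t12), np.cos(t12)
    Jd = np.empty(theta.shape[:-1] + (2, 2))
    Jd[..., 0, 0] = -L1 * c1 * d1 - L2 * c12 * d12
    Jd[..., 0, 1] = -L2 * c12 * d12
    Jd[..., 1, 0] = -L1 * s1 * d1 - L2 * s12 * d12
    Jd[..., 1, 1] = -L2 * s12 * d12
    return Jd


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def inertia_matrix(theta2: np.ndarray, params: PhysicalParams) -> np.ndarray:
    """Configuration-dependent inertia matrix M(theta), shape (..., 2, 2)."""
    theta2 = np.asarray(theta2, dtype=float)
    c2 = np.cos(theta2)
    M = np.empty(theta2.shape + (2, 2))
    M[..., 0, 0] = params.I1 + params.I2 + params.m2 * (
        params.L1 ** 2 + 2.0 * params.L1 * params.S2 * c2
    )
    M[..., 0, 1] = params.I2 + params.m2 * params.L1 * params.S2 * c2
    M[..., 1, 0] = M[..., 0, 1]
    M[..., 1, 1] = params.I2
    return M


def interaction_torque(
    theta2: np.ndarray, dtheta: np.ndarray, params: PhysicalParams
) -> np.ndarray:
    """Coriolis + centrifugal torque h1[th1'th2'] + h2[th'^2], shape (..., 2)."""
    theta2 = np.asarray(theta2, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    a = params.m2 * params.L1 * params.S2 * np.sin(theta2)
    d1, d2 = dtheta[..., 0], dtheta[..., 1]
    return np.stack([-a * (2.0 * d1 * d2 + d2 ** 2), a * d1 ** 2], axis=-1)


def inverse_dynamics(
    theta: np.ndarray,
    dtheta: np.ndarray,
    ddtheta: np.ndarray,
    params: PhysicalParams,
    include_interaction: bool = True,
) -> np.ndarray:
    """Joint torque realizing a joint-space trajectory (horizontal plane).

    All angle arrays have shape (..., 2); the torque has the same shape.
    ``include_interaction=False`` drops the Coriolis/centrifugal terms.
    """
    theta = np.asarray(theta, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    ddtheta = np.asarray(ddtheta, dtype=float)
    if not theta.shape == dtheta.shape == ddtheta.shape:
        raise ValueError("theta, dtheta, ddtheta must have identical shapes")
    M = inertia_matrix(theta[..., 1], params)
    tau = np.einsum("...ij,...j->...i", M, ddtheta)
    if include_interaction:
        tau += interaction_torque(theta[..., 1], dtheta, params)
    tau += dtheta @ params.B.T
    return tau


def _accel(
    theta: np.ndarray,
    dtheta: np.ndarray,
    tau: np.ndarray,
    params: PhysicalParams,
    include_interaction: bool,
) -> np.ndarray:
    """ddtheta = M^-1 (tau - interaction - B dtheta); closed-form 2x2 solve."""
    t2 = theta[..., 1]
    c2 = np.cos(t2)
    m11 = params.I1 + params.I2 + params.m2 * (
        params.L1 ** 2 + 2.0 * params.L1 * params.S2 * c2
    )
    m12 = params.I2 + params.m2 * params.L1 * params.S2 * c2
    m22 = params.I2
    rhs = tau - dtheta @ params.B.T
    if include_interaction:
        rhs = rhs - interaction_torque(t2, dtheta, params)
    det = m11 * m22 - m12 * m12
    if np.any(det <= 0):
        raise FloatingPointError("inertia matrix not positive definite")
    r1, r2 = rhs[..., 0], rhs[..., 1]
    return np.stack(
        [(m22 * r1 - m12 * r2) / det, (m11 * r2 - m12 * r1) / det], axis=-1
    )


def forward_dynamics(
    torque: TorqueSeries | Callable[[float], np.ndarray],
    theta0: np.ndarray,
    dtheta0: np.ndarray,
    params: PhysicalParams,
    dt: float = 1e-3,
    t_end: float | None = None,
    include_interaction: bool = True,
):
    """Integrate the equation of motion under a torque input.

    Parameters
    ----------
    torque : TorqueSeries or callable
        Torque input; a series is interpolated linearly between samples.
    theta0, dtheta0 : array-like, shape (2,)
        Initial joint angles and velocities.
    dt : float
        Integrator step (s).  Classical fourth-order Runge-Kutta.
    t_end : float, optional
        End of the integration window; defaults to the end of the series.

    Returns
    -------
    t, theta, dtheta : ndarray
        Time grid and the integrated joint state series.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if isinstance(torque, TorqueSeries):
        ts = torque
        if t_end is None:
            t_end = float(ts.t[-1])
        if t_end > ts.t[-1] + 1e-12:
            raise ValueError("torque grid does not cover the integration window")

        def tau_of(t: float) -> np.ndarray:
            return np.array(
                [np.interp(t, ts.t, ts.tau[:, 0]), np.interp(t, ts.t, ts.tau[:, 1])]
            )
    else:
        if t_end is None:
            raise ValueError("t_end is required with a torque callable")
        tau_of = torque

    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    theta = np.empty((n + 1, 2))
    dtheta = np.empty((n + 1, 2))
    theta[0] = np.asarray(theta0, dtype=float)
    dtheta[0] = np.asarray(dtheta0, dtype=float)
    for j in range(n):
        tj = t[j]
        th, dth = theta[j], dtheta[j]
        tau_a = tau_of(tj)
        tau_m = tau_of(tj + 0.5 * dt)
        tau_b = tau_of(tj + dt)
        k1v = _accel(th, dth, tau_a, params, include_interaction)
        k1x = dth
        k2v = _accel(th + 0.5 * dt * k1x, dth + 0.5 * dt * k1v, tau_m,
                     params, include_interaction)
        k2x = dth + 0.5 * dt * k1v
        k3v = _accel(th + 0.5 * dt * k2x, dth + 0.5 * dt * k2v, tau_m,
                     params, include_interaction)
        k3x = dth + 0.5 * dt * k2v
        k4v = _accel(th + dt * k3x, dth + dt * k3v, tau_b,
                     params, include_interaction)
        k4x = dth + dt * k3v
        theta[j + 1] = th + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        dtheta[j + 1] = dth + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return t, theta, dtheta


# ---------------------------------------------------------------------------
# anthropometry
# ---------------------------------------------------------------------------

#: Reference arm-segment parameters for 11 adults (columns: upper-arm and
#: forearm length L (m), joint-to-centre-of-mass distance S (m), mass m (kg,
#: forearm including the 0.740 kg air-sled attachment) and moment of inertia
#: about the joint I (kg m^2).  Used to calibrate the proportionality
#: coefficients below; shipped as data so the fit is reproducible.
REFERENCE_ARM_TABLE = {
    "L1": [0.302, 0.270, 0.264, 0.261, 0.266, 0.308, 0.274, 0.278, 0.296, 0.303, 0.282],
    "L2": [0.325, 0.315, 0.335, 0.335, 0.312, 0.350, 0.316, 0.319, 0.345, 0.360, 0.332],
    "S1": [0.114, 0.101, 0.098, 0.097, 0.099, 0.116, 0.102, 0.104, 0.111, 0.114, 0.106],
    "S2": [0.159, 0.155, 0.164, 0.164, 0.153, 0.170, 0.155, 0.156, 0.168, 0.175, 0.162],
    "m1": [1.506, 1.332, 1.299, 1.283, 1.310, 1.538, 1.354, 1.375, 1.473, 1.511, 1.397],
    "m2": [1.794, 1.764, 1.824, 1.824, 1.755, 1.868, 1.767, 1.776, 1.853, 1.898, 1.815],
    "I1": [0.030, 0.021, 0.019, 0.019, 0.020, 0.032, 0.022, 0.023, 0.028, 0.030, 0.024],
    "I2": [0.040, 0.037, 0.043, 0.043, 0.036, 0.049, 0.037, 0.038, 0.047, 0.053, 0.042],
}

#: Mean link lengths (m) of the reference table, with their SDs; used by the
#: synthetic subject generator.
REFERENCE_ARM_LENGTHS = {
    "L1": (0.282, 0.017),
    "L2": (0.331, 0.016),
}

#: Direction-specific joint viscosity matrices (kg m^2/s): reference means
#: estimated during static force control toward each target direction.
_VISCOSITY_TABLE = {
    "front": (0.690, 0.181, 0.790),
    "back": (0.674, 0.186, 0.816),
    "left": (0.740, 0.180, 0.787),
    "right": (0.715, 0.181, 0.790),
}


def default_viscosity(direction: str) -> np.ndarray:
    """Reference 2x2 joint viscosity matrix for a reach direction.

    ``direction`` is one of ``front``/``back``/``left``/``right`` (the four
    centre-out target directions 90/270/180/0 degrees).
    """
    try:
        b11, b12, b22 = _VISCOSITY_TABLE[direction.lower()]
    except KeyError:
        raise ValueError(
            f"unknown direction {direction!r}; expected one of "
            f"{sorted(_VISCOSITY_TABLE)}"
        ) from None
    return np.array([[b11, b12], [b12, b22]])


def fit_anthropometric_coefficients(table: dict | None = None) -> dict:
    """Least-squares proportionality coefficients from a reference table.

    Fits, across subjects, S_i = cS_i L_i, m_i = cm_i L_i (forearm mass with
    the air-sled removed first) and I_i = cI_i m_i L_i^2 (forearm inertia
    against the sled-inclusive mass, matching how the reference inertias
    were tabulated).  Relative least squares is used so each subject
    contributes equally regardless of scale.
    """
    tab = {k: np.asarray(v, dtype=float) for k, v in (table or REFERENCE_ARM_TABLE).items()}

    def rel_ls(x: np.ndarray, y: np.ndarray) -> float:
        # minimize sum((c*x - y)^2 / y^2)  ->  c = sum(x/y) / sum(x^2/y^2)
        return float(np.sum(x / y) / np.sum((x / y) ** 2))

    m2_bare = tab["m2"] - AIR_SLED_MASS
    return {
        "cS1": rel_ls(tab["L1"], tab["S1"]),
        "cS2": rel_ls(tab["L2"], tab["S2"]),
        "cm1": rel_ls(tab["L1"], tab["m1"]),
        "cm2": rel_ls(tab["L2"], m2_bare),
        "cI1": rel_ls(tab["m1"] * tab["L1"] ** 2, tab["I1"]),
        "cI2": rel_ls(tab["m2"] * tab["L2"] ** 2, tab["I2"]),
    }


DEFAULT_ANTHRO_COEFFS = fit_anthropometric_coefficients()


def estimate_physical_params(
    L1: float,
    L2: float,
    attached_mass: float = AIR_SLED_MASS,
    coefficients: dict | None = None,
    B: np.ndarray | None = None,
) -> PhysicalParams:
    """Estimate full arm parameters from the two link lengths.

    Centre-of-mass offsets and masses scale linearly with link length;
    moments of inertia scale with m L^2.  ``attached_mass`` (default the
    0.740 kg air-sled) is added to the forearm mass before the forearm
    inertia coefficient is applied.  ``B`` defaults to the front-direction
    reference viscosity.
    """
    _check_lengths(L1, L2)
    if attached_mass < 0:
        raise ValueError("attached_mass must be >= 0")
    c = coefficients or DEFAULT_ANTHRO_COEFFS
    m1 = c["cm1"] * L1
    m2 = c["cm2"] * L2 + attached_mass
    return PhysicalParams(
        L1=L1,
        L2=L2,
        S1=c["cS1"] * L1,
        S2=c["cS2"] * L2,
        m1=m1,
        m2=m2,
        I1=c["cI1"] * m1 * L1 ** 2,
        I2=c["cI2"] * m2 * L2 ** 2,
        B=default_viscosity("front") if B is None else np.asarray(B, dtype=float),
    )
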