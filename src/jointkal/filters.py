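"""Kalman filtering of joint trajectories.

State: X = [x, y, z, vx, vy, vz] (meters, m/s), constant-velocity dynamics
X_{k+1} = F X_k + w_k with frame interval T (1/30 s at 30 Hz).  Measurement:
either the raw 3-D position, or the position augmented with the sound-source
bearing arctan(x/z) reported by the sensor's microphone array.  The bearing
makes the measurement nonlinear, so its row is linearized about the
prediction (extended Kalman filter); the innovation itself uses the
nonlinear h and the bearing residual is wrapped to (-pi, pi].

Also provides the two standard comparison baselines: a centered moving-mean
filter and the traditional linear (position-only) Kalman filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FilterNumericalError, SingularGeometryError, ValidationError

__all__ = [
    "FilterModel",
    "FilterState",
    "Measurement",
    "predict",
    "measurement_jacobian",
    "update",
    "ekf_smooth",
    "moving_mean_filter",
    "linear_kalman_filter",
]


@dataclass(frozen=True)
class FilterModel:
    """Constant-velocity model and noise covariances.

    dt : seconds
        Frame interval; 1/30 by default (30 Hz skeleton stream).
    sigma_a : m/s^2
        White-acceleration intensity of the process noise.  The default of
        0.3 brackets the centripetal acceleration of unhurried arm movement
        (~0.1 m/s^2) while keeping the steady-state measurement gain low
        enough for effective jitter smoothing.
    sigma_p : meters
        Assumed position-measurement noise, per axis.
    sigma_theta_deg : degrees
        Assumed sound-bearing measurement noise.
    """

    dt: float = 1.0 / 30.0
    sigma_a: float = 0.3
    sigma_p: float = 0.01
    sigma_theta_deg: float = 2.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")
        if self.sigma_a < 0:
            raise ValidationError("sigma_a must be >= 0")
        if min(self.sigma_p, self.sigma_theta_deg) <= 0:
            raise ValidationError("measurement noise intensities must be > 0")

    @property
    def F(self) -> np.ndarray:
        """6x6 state transition: position integrates velocity over dt."""
        F = np.eye(6)
        F[0, 3] = F[1, 4] = F[2, 5] = self.dt
        return F

    @property
    def Q(self) -> np.ndarray:
        """Discrete white-noise-acceleration process covariance (per axis)."""
        t, q = self.dt, self.sigma_a**2
        Q = np.zeros((6, 6))
        for i in range(3):
            Q[i, i] = q * t**4 / 4.0
            Q[i, i + 3] = Q[i + 3, i] = q * t**3 / 2.0
            Q[i + 3, i + 3] = q * t**2
        return Q

    def R(self, with_angle: bool) -> np.ndarray:
        """Measurement covariance: 3x3 position-only or 4x4 with bearing."""
        diag = [self.sigma_p**2] * 3
        if with_angle:
            diag.append(np.radians(self.sigma_theta_deg) ** 2)
        return np.diag(diag)

    def h(self, x: np.ndarray, with_angle: bool) -> np.ndarray:
        """Measurement function: position, optionally plus bearing arctan(x/z)."""
        if not with_angle:
            return x[:3].copy()
        return np.array([x[0], x[1], x[2], np.arctan2(x[0], x[2])])

    def initial_state(self, position: np.ndarray,
                      pos_var: float = 0.1**2, vel_var: float = 0.1**2) -> "FilterState":
        """State at the first frame: measured position, zero velocity."""
        x = np.zeros(6)
        x[:3] = np.asarray(position, dtype=float)
        P = np.diag([pos_var] * 3 + [vel_var] * 3)
        return FilterState(x=x, P=P)


@dataclass
class FilterState:
    """State mean X = [x, y, z, vx, vy, vz] and covariance P."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(6)
        self.P = np.asarray(self.P, dtype=float).reshape(6, 6)

    @property
    def position(self) -> np.ndarray:
        return self.x[:3]

    @property
    def velocity(self) -> np.ndarray:
        return self.x[3:]


@dataclass(frozen=True)
class Measurement:
    """A single frame's observation: 3-D position, optional bearing (radians)."""

    position: np.ndarray
    sound_angle: float | None = None


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def predict(state: FilterState, model: FilterModel) -> FilterState:
    """Time update: X- = F X, P- = F P F^T + Q."""
    F = model.F
    return FilterState(x=F @ state.x, P=_symmetrize(F @ state.P @ F.T + model.Q))


def measurement_jacobian(state: FilterState) -> np.ndarray:
    """4x6 Jacobian of [x, y, z, arctan(x/z)] at the current state.

    Rows 1-3 select position.  Row 4 holds the analytic partials of the
    bearing: d/dx = z/(x^2+z^2), d/dz = -x/(x^2+z^2).
    """
    x, z = state.x[0], state.x[2]
    r2 = x * x + z * z
    if r2 == 0.0 or z == 0.0:
        raise SingularGeometryError("bearing Jacobian undefined at z = 0")
    H = np.zeros((4, 6))
    H[0, 0] = H[1, 1] = H[2, 2] = 1.0
    H[3, 0] = z / r2
    H[3, 2] = -x / r2
    return H


def _position_jacobian() -> np.ndarray:
    H = np.zeros((3, 6))
    H[0, 0] = H[1, 1] = H[2, 2] = 1.0
    return H


def update(state: FilterState, meas: Measurement, model: FilterModel) -> FilterState:
    """Measurement update K = P- H^T (H P- H^T + R)^-1 applied to a prediction.

    The innovation uses the nonlinear h at the prediction for the bearing
    row, with the angular residual wrapped to (-pi, pi]; the gain and the
    covariance update use the Jacobian H.
    """
    with_angle = meas.sound_angle is not None
    if with_angle:
        H = measurement_jacobian(state)
        y = np.array([*np.asarray(meas.position, dtype=float), float(meas.sound_angle)])
    else:
        H = _position_jacobian()
        y = np.asarray(meas.position, dtype=float)
    R = model.R(with_angle)
    S = H @ state.P @ H.T + R
    try:
        K = np.linalg.solve(S.T, (state.P @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise FilterNumericalError(
            f"singular innovation covariance (cond ~ {np.linalg.cond(S):.2e})") from exc
    innovation = y - model.h(state.x, with_angle)
    if with_angle:
        innovation[3] = (innovation[3] + np.pi) % (2.0 * np.pi) - np.pi
    x_new = state.x + K @ innovation
    P_new = _symmetrize((np.eye(6) - K @ H) @ state.P)
    return FilterState(x=x_new, P=P_new)


def ekf_smooth(traj: np.ndarray, angles: np.ndarray | None = None,
               model: FilterModel | None = None,
               init: FilterState | None = None) -> np.ndarray:
    """Run predict/update over a trajectory; returns posterior positions.

    ``angles`` (radians, NaN = absent) enables the bearing channel per
    frame.  Frames with a non-finite position receive no measurement update
    (prediction only).  Initialization defaults to the first finite
    position with zero velocity.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValidationError("trajectory must have shape (n, 3)")
    if traj.shape[0] < 1:
        raise ValidationError("need at least one frame")
    model = model or FilterModel()
    if init is None:
        finite = np.isfinite(traj).all(axis=1)
        if not finite.any():
            raise ValidationError("no finite positions to initialize from")
        init = model.initial_state(traj[np.argmax(finite)])
    state = init
    out = np.empty_like(traj)
    for f in range(traj.shape[0]):
        state = predict(state, model)
        if np.isfinite(traj[f]).all():
            angle = None
            if angles is not None and np.isfinite(angles[f]):
                angle = float(angles[f])
            state = update(state, Measurement(traj[f], angle), model)
        out[f] = state.position
    return out


def moving_mean_filter(traj: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average per coordinate, truncated at the sequence ends."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2:
        raise ValidationError("trajectory must be 2-D")
    if window == 1:
        return traj.copy()
    return (pd.DataFrame(traj)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy())


def linear_kalman_filter(traj: np.ndarray, model: FilterModel | None = None,
                         init: FilterState | None = None) -> np.ndarray:
    """Traditional linear Kalman filter: position-only measurement, no bearing."""
    return ekf_smooth(traj, angles=None, model=model, init=init)
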