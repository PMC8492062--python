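"""Musculoskeletal model: muscle cells, body angles, midline, motor output.

Each motoneuron drives a passive RC muscle cell (one per model somite per
side).  Local body angles follow a chain of uncoupled damped pendulums forced
by the left-right difference in muscle potential::

    theta'' + 2 zeta omega0 theta' + omega0^2 theta = g (VR - VL)

Positive angles are rightward curvatures.  The body midline is reconstructed
link by link from the angles, and the integrated motor output is the summed
bilateral muscle activity convolved with a 50 ms boxcar.

The RC constants and the motoneuron-to-muscle weights are model-stage
constants; ``g`` (forcing gain), ``zeta`` and ``omega0`` are calibration
parameters of the body model (see the parameter sheets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "MuscleParams",
    "BodyParams",
    "BodyKinematics",
    "muscle_step",
    "pendulum_step",
    "compute_midline",
    "integrated_motor_output",
    "body_kinematics",
]

BOXCAR_MS = 50.0


@dataclass(frozen=True)
class MuscleParams:
    """Passive RC membrane of one muscle cell plus its neuromuscular weight."""

    R: float
    C: float
    mn_weight: float

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0:
            raise ValueError("R and C must be positive")


@dataclass(frozen=True)
class BodyParams:
    """Damped-pendulum chain parameters.

    ``zeta`` damping ratio, ``omega0`` natural frequency in rad/ms, ``gain``
    the forcing coefficient from muscle-potential difference to angular
    acceleration, ``segment_length`` the midline link length (a.d.u.), and
    ``somites_per_muscle`` the number of biological somites one muscle cell
    stands for (reporting only).
    """

    zeta: float
    omega0: float
    gain: float
    segment_length: float
    n_segments: int
    somites_per_muscle: int = 1

    def __post_init__(self) -> None:
        if self.zeta <= 0 or self.omega0 <= 0 or self.segment_length <= 0:
            raise ValueError("zeta, omega0 and segment_length must be positive")


@dataclass
class BodyKinematics:
    """Per-muscle-cell potentials, body angles and derived motor output."""

    t: np.ndarray  # ms
    VL: np.ndarray  # (n_cells, T) left muscle potentials
    VR: np.ndarray  # (n_cells, T)
    theta: np.ndarray  # (n_cells, T) rad, positive = rightward curvature
    tail_y: np.ndarray  # (T,) lateral displacement of the most caudal point
    integrated: np.ndarray  # (T,) integrated motor output
    dt: float
    body: BodyParams


def muscle_step(v: float, i_syn: float, R: float, C: float, dt: float) -> float:
    """One Euler step of the passive RC muscle membrane V' = -V/(RC) + I/C."""
    if R <= 0 or C <= 0:
        raise ValueError("R and C must be positive")
    return v + dt * (-v / (R * C) + i_syn / C)


def pendulum_step(
    theta: float,
    dtheta: float,
    v_right: float,
    v_left: float,
    params: BodyParams,
    dt: float,
) -> tuple[float, float]:
    """One Euler step of a single damped pendulum segment."""
    acc = (
        params.gain * (v_right - v_left)
        - 2.0 * params.zeta * params.omega0 * dtheta
        - params.omega0**2 * theta
    )
    return theta + dt * dtheta, dtheta + dt * acc


def compute_midline(theta: np.ndarray, segment_length: float) -> np.ndarray:
    """Body midline points from per-segment angles.

    Returns an ``(n_segments + 1, 2)`` array starting at the origin with
    ``x_i = x_{i-1} + l cos(theta_i)`` and ``y_i = y_{i-1} - l sin(theta_i)``,
    so positive (rightward) angles bend the midline toward negative y.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite body angle")
    pts = np.zeros((len(theta) + 1, 2))
    pts[1:, 0] = np.cumsum(segment_length * np.cos(theta))
    pts[1:, 1] = np.cumsum(-segment_length * np.sin(theta))
    return pts


def integrated_motor_output(
    VL: np.ndarray,
    VR: np.ndarray,
    dt: float,
    boxcar_ms: float = BOXCAR_MS,
    normalize: bool = False,
) -> np.ndarray:
    """Summed bilateral muscle activity convolved with a unit-amplitude boxcar.

    With ``normalize=True`` the sum is divided by the number of muscle cells,
    so the trace reads as per-cell activity smoothed over the boxcar window;
    the episode-detection threshold of 0.5 arbitrary units applies to this
    normalized trace.
    """
    VL, VR = np.asarray(VL), np.asarray(VR)
    total = VL.sum(axis=0) + VR.sum(axis=0)
    if normalize:
        total = total / (VL.shape[0] + VR.shape[0])
    width = max(1, int(round(boxcar_ms / dt)))
    return np.convolve(total, np.ones(width), mode="same")


def _muscle_filter(i_syn: np.ndarray, R: float, C: float, dt: float) -> np.ndarray:
    # Euler recursion V[s+1] = (1 - dt/RC) V[s] + (dt/C) I[s] as an IIR filter
    return lfilter([0.0, dt / C], [1.0, -(1.0 - dt / (R * C))], i_syn, axis=-1)


def _pendulum_filter(force: np.ndarray, p: BodyParams, dt: float) -> np.ndarray:
    a1 = -(2.0 - 2.0 * p.zeta * p.omega0 * dt)
    a2 = 1.0 - 2.0 * p.zeta * p.omega0 * dt + (p.omega0 * dt) ** 2
    return lfilter([0.0, 0.0, p.gain * dt * dt], [1.0, a1, a2], force, axis=-1)


def body_kinematics(result, body_overrides: dict | None = None) -> BodyKinematics:
    """Integrate muscle membranes and body angles from a simulation result.

    ``result`` is a :class:`~coilswim.engine.SimulationResult`; the muscle RC
    constants and body parameters come from the model (overridable here).
    """
    model = result.model
    cfg = dict(model.body)
    cfg.update(body_overrides or {})
    body = BodyParams(
        zeta=cfg["zeta"],
        omega0=cfg["omega0"],
        gain=cfg["gain"],
        segment_length=cfg["segment_length"],
        n_segments=model.n_muscle_cells,
        somites_per_muscle=cfg.get("somites_per_muscle", 1),
    )
    dt = result.dt
    IL, IR = result.muscle_input[0], result.muscle_input[1]
    VL = _muscle_filter(IL.astype(float), model.muscle_R, model.muscle_C, dt)
    VR = _muscle_filter(IR.astype(float), model.muscle_R, model.muscle_C, dt)
    theta = _pendulum_filter(VR - VL, body, dt)
    tail_y = -body.segment_length * np.sin(theta).sum(axis=0)
    integrated = integrated_motor_output(VL, VR, dt, normalize=True)
    t = np.arange(VL.shape[1]) * dt
    return BodyKinematics(
        t=t, VL=VL, VR=VR, theta=theta, tail_y=tail_y,
        integrated=integrated, dt=dt, body=body,
    )


def angle_heatmap_frame(kin: BodyKinematics, stride: int = 10) -> pd.DataFrame:
    """Time-by-segment body-angle matrix (rad) for CSV export or plotting."""
    sub = kin.theta[:, ::stride]
    return pd.DataFrame(
        sub.T,
        index=pd.Index(kin.t[::stride], name="time_ms"),
        columns=[f"segment_{i + 1}" for i in range(kin.theta.shape[0])],
    )
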