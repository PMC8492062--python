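"""Single-compartment spiking neurons and population layout.

Each neuron follows the two-variable quadratic integrate-and-fire dynamics of
Izhikevich (2007)::

    C V' = k (V - Vr)(V - Vt) - u + Isyn
      u' = a (b (V - Vr) - u)
    if V >= Vmax:  V <- c,  u <- u + d   (a spike is recorded)

with forward-Euler integration at a fixed 0.1 ms time step.  Parameter sets for
every (population, model-variant) pair are shipped as YAML sheets under
``coilswim/params`` and loaded by :func:`coilswim.circuits.load_params`.

Populations are point neurons arranged on a rostrocaudal axis: ``x = offset +
spacing * n`` in arbitrary distance units (one model somite = 1.6 a.d.u.),
``y = +1`` on the right and ``-1`` on the left side of the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "PopulationSpec",
    "neuron_derivatives",
    "euler_step",
    "make_population",
]

PARAM_FIELDS = ("a", "b", "c", "d", "vmax", "vr", "vt", "k", "C")


@dataclass(frozen=True)
class IzhikevichParams:
    """Membrane-dynamics parameters of one neuron model.

    ``a`` (1/ms) recovery timescale, ``b`` coupling of u to V, ``c`` (mV)
    post-spike reset, ``d`` post-spike recovery increment, ``vmax`` (mV) spike
    peak, ``vr``/``vt`` (mV) resting and firing-threshold potentials, ``k``
    subthreshold I-V coefficient and ``C`` membrane capacitance.
    """

    a: float
    b: float
    c: float
    d: float
    vmax: float
    vr: float
    vt: float
    k: float
    C: float

    def __post_init__(self) -> None:
        if not (self.vr < self.vt < self.vmax):
            raise ValueError(
                f"require vr < vt < vmax, got {self.vr}, {self.vt}, {self.vmax}"
            )
        if self.C <= 0:
            raise ValueError("capacitance must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)


@dataclass
class NeuronState:
    """Instantaneous membrane state ``(V, u)`` of one neuron."""

    V: float
    u: float
    spiked: bool = False


@dataclass
class PopulationSpec:
    """A homogeneous population on one side of the body.

    ``kind`` is one of IC, MN, V0d, dI6, V0v, V2a, V1 (or Muscle); positions
    follow ``x = offset + spacing * n`` with n = 0..count-1 and ``y = +1``
    (right) or ``-1`` (left).  ``drive`` is the tonic motor-command amplitude
    delivered to every member from ``drive_onset`` ms onward.
    """

    kind: str
    side: str
    count: int
    params: IzhikevichParams
    x: np.ndarray
    y: np.ndarray
    drive: float = 0.0
    drive_onset: float = 0.0
    first_segment: int = 1  # 1-based segment of member n=0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")
        if len(self.x) != self.count or len(self.y) != self.count:
            raise ValueError("position arrays must match count")
        if np.any(np.abs(self.y) != 1.0):
            raise ValueError("|y| must be 1 a.d.u.")
        if self.count > 1 and self.x[1] > self.x[0] and np.any(np.diff(self.x) <= 0):
            raise ValueError("positions must be strictly increasing in n")

    def segments(self) -> np.ndarray:
        """1-based body segment of each member (rostral to caudal)."""
        return np.arange(self.count) + self.first_segment


def neuron_derivatives(
    state: NeuronState, params: IzhikevichParams, i_syn: float
) -> tuple[float, float]:
    """Right-hand side ``(dV/dt, du/dt)`` of the membrane equations."""
    v, u = state.V, state.u
    if not (np.isfinite(v) and np.isfinite(u) and np.isfinite(i_syn)):
        raise FloatingPointError(
            f"non-finite membrane state or current (V={v}, u={u}, Isyn={i_syn})"
        )
    dv = (params.k * (v - params.vr) * (v - params.vt) - u + i_syn) / params.C
    du = params.a * (params.b * (v - params.vr) - u)
    return dv, du


def euler_step(
    state: NeuronState, params: IzhikevichParams, i_syn: float, dt: float
) -> NeuronState:
    """One forward-Euler step; applies the spike reset when V reaches Vmax.

    The spike is recorded at the step where the updated V first reaches Vmax;
    the stored trace value is clamped at Vmax at that sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dv, du = neuron_derivatives(state, params, i_syn)
    v = state.V + dt * dv
    u = state.u + dt * du
    if v >= params.vmax:
        return NeuronState(V=params.c, u=u + params.d, spiked=True)
    return NeuronState(V=v, u=u, spiked=False)


def make_population(
    kind: str,
    model_variant: str,
    side: str,
    count: int | None = None,
    overrides: dict | None = None,
) -> PopulationSpec:
    """Build a PopulationSpec for a named (population, model-variant) pair.

    Parameters come from the model variant's parameter sheet; ``count`` and any
    Izhikevich parameter can be overridden.  Raises ``KeyError`` for a pair the
    sheets do not define.
    """
    from .circuits import load_params  # local import to avoid a cycle

    sheet = load_params(model_variant)
    try:
        spec = sheet["populations"][kind]
    except KeyError:
        raise KeyError(
            f"population {kind!r} is not defined for model {model_variant!r}"
        ) from None
    izhi = dict(spec["izhikevich"])
    if overrides:
        izhi.update({k: v for k, v in overrides.items() if k in PARAM_FIELDS})
    n = count if count is not None else spec["count"]
    pos = spec["position"]
    x = pos["offset"] + pos["spacing"] * np.arange(n, dtype=float)
    y = np.full(n, 1.0 if side == "right" else -1.0)
    drive = spec["drive"]["left" if side == "left" else "right"]
    onset = spec["drive"].get("onset", 0.0)
    if side == "right":
        onset = spec["drive"].get("right_onset", onset)
    first_segment = 2 if kind == "V1" else 1
    return PopulationSpec(
        kind=kind,
        side=side,
        count=n,
        params=IzhikevichParams(**izhi),
        x=x,
        y=y,
        drive=float(drive),
        drive_onset=float(onset),
        first_segment=first_segment,
    )
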