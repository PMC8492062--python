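"""Time-stepping of a :class:`~coilswim.circuits.CircuitModel`.

The engine accumulates gap-junction currents (Ohmic, driven by the delayed
presynaptic deviation from rest minus the postsynaptic one by default; see
``CircuitModel.gap_mode``), delayed event-triggered chemical currents (whose
weights act on the voltage rate, i.e. are scaled by the postsynaptic
capacitance), and tonic drives; integrates every neuron by forward Euler at
dt = 0.1 ms; and records membrane traces, spike times, and the synaptic
input currents of the muscle cells.  Chemical synapses are disabled during
the first 50 ms of every simulation so initial conditions can dissipate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .circuits import GAP, GLUT, GLY, CircuitModel
from .neurons import PARAM_FIELDS

__all__ = ["SimulationResult", "run", "gap_current", "chem_current"]

CHEM_OFF_MS = 50.0  # chemical synapses silent at the start of every simulation


def gap_current(v_pre: float, g: float, v_post: float | None = None) -> float:
    """Ohmic gap-junction current.

    With ``v_post`` omitted this is the plain product ``Vpre * G`` as the
    Ohmic law is usually printed; passing the postsynaptic potential gives
    the transjunctional difference form ``(Vpre - Vpost) * G``, which is what
    the engine's default deviation-coupled mode reduces to between neurons
    with equal resting potentials.
    """
    if v_post is None:
        return v_pre * g
    return (v_pre - v_post) * g


def chem_current(
    v_post: float,
    e_rev: float,
    t: float,
    t0: float | None,
    tau_r: float,
    tau_f: float,
    w: float,
) -> float:
    """Event-triggered chemical synaptic current (zero before any trigger)."""
    if t0 is None or t < t0:
        return 0.0
    s = t - t0
    kernel = math.exp(-s / tau_r) - math.exp(-s / tau_f)
    return (v_post - e_rev) * kernel * w


@dataclass
class SimulationResult:
    """Time-aligned output of one network simulation."""

    model: CircuitModel
    duration: float
    dt: float
    stride: int
    seed: int
    t: np.ndarray  # stored time grid (ms)
    V: np.ndarray | None  # (n_stored, n_neurons) float32, or None
    spikes: list[np.ndarray]  # spike times (ms) per neuron
    muscle_input: np.ndarray  # (2, n_cells, n_steps) float32 input currents

    @property
    def n_neurons(self) -> int:
        return self.model.n_neurons

    def spike_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def pop_spikes(self, kind: str, side: str) -> list[np.ndarray]:
        sl = self.model.pop_slice(kind, side)
        return self.spikes[sl]

    def save(self, path) -> None:
        """Persist as a compressed array container with a JSON metadata sidecar."""
        from pathlib import Path

        path = Path(path)
        arrays = {
            "t": self.t,
            "muscle_input": self.muscle_input,
            "spike_times": np.concatenate(self.spikes) if self.spikes else np.empty(0),
            "spike_ids": np.concatenate(
                [np.full(len(s), i) for i, s in enumerate(self.spikes)]
            )
            if self.spikes
            else np.empty(0, dtype=int),
        }
        if self.V is not None:
            arrays["V"] = self.V
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "model": self.model.name,
            "duration_ms": self.duration,
            "dt_ms": self.dt,
            "stride": self.stride,
            "seed": self.seed,
            "n_neurons": self.n_neurons,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _compile_arrays(model: CircuitModel):
    """Flatten the model into the typed arrays the kernel consumes."""
    n = model.n_neurons
    params = np.zeros((n, len(PARAM_FIELDS)))
    drive = np.zeros(n)
    onset = np.zeros(n)
    start = 0
    for p in model.populations:
        params[start : start + p.count] = p.params.as_array()
        drive[start : start + p.count] = p.drive
        onset[start : start + p.count] = p.drive_onset
        start += p.count
    if model.param_scales is not None:
        params = params * model.param_scales

    dt = model.dt
    gaps = [c for c in model.connections if c.kind == GAP]
    chems = [c for c in model.connections if c.kind in (GLUT, GLY)]
    g_pre = np.array([c.pre for c in gaps], dtype=np.int64)
    g_post = np.array([c.post for c in gaps], dtype=np.int64)
    g_w = np.array(
        [c.weight * (model.gap_scale if c.reciprocal else 1.0) for c in gaps]
    )
    g_del = np.array([round(c.delay / dt) for c in gaps], dtype=np.int64)
    c_pre = np.array([c.pre for c in chems], dtype=np.int64)
    c_post = np.array([c.post for c in chems], dtype=np.int64)
    c_w = np.array([c.weight for c in chems])
    if model.chem_per_capacitance:
        # weights act on dV/dt directly; convert to current by C_post
        c_w = c_w * params[[c.post for c in chems], 8]
    c_del = np.array([round(c.delay / dt) * dt for c in chems])
    c_erev = np.array(
        [model.e_gly if c.kind == GLY else model.e_glut for c in chems]
    )
    c_gly = np.array([c.kind == GLY for c in chems], dtype=np.bool_)

    n_cells = model.n_muscle_cells
    m_pre = np.array([c.pre for c in model.muscle_synapses], dtype=np.int64)
    m_idx = np.array(
        [c.post - n for c in model.muscle_synapses], dtype=np.int64
    )  # 0..2*n_cells-1, left block then right block
    m_w = np.array([c.weight for c in model.muscle_synapses])
    L = int(max(g_del.max() if len(gaps) else 0, 1)) + 2
    return (
        params, drive, onset,
        g_pre, g_post, g_w, g_del,
        c_pre, c_post, c_w, c_del, c_erev, c_gly,
        m_pre, m_idx, m_w,
        n_cells, L,
    )


def _compile_perturbations(model: CircuitModel, perturbations):
    """Turn PerturbationPlans into masks and epoch windows for the kernel."""
    n = model.n_neurons
    sil_masks, sil_epochs = [], []
    gly_epochs, glut_epochs = [], []
    sil_gap_too = True
    for plan in perturbations or ():
        if plan.kind == "silence_population":
            mask = np.zeros(n, dtype=np.bool_)
            found = False
            for side in ("left", "right"):
                try:
                    mask[model.pop_slice(plan.target, side)] = True
                    found = True
                except KeyError:
                    pass
            if not found:
                raise KeyError(
                    f"population {plan.target!r} not present in model {model.name!r}"
                )
            sil_gap_too = plan.include_gap
            for start, end in plan.epochs:
                sil_masks.append(mask)
                sil_epochs.append((start, end))
        elif plan.kind == "block_glycine":
            gly_epochs.extend(plan.epochs)
        elif plan.kind == "block_glutamate":
            glut_epochs.extend(plan.epochs)
        else:
            raise ValueError(f"unknown perturbation kind {plan.kind!r}")
    sil_mask = (
        np.array(sil_masks, dtype=np.bool_)
        if sil_masks
        else np.zeros((0, n), dtype=np.bool_)
    )
    as_arr = lambda e: np.array(e, dtype=float).reshape(-1, 2)
    return (
        sil_mask,
        as_arr(sil_epochs) if sil_epochs else np.zeros((0, 2)),
        sil_gap_too,
        as_arr(gly_epochs) if gly_epochs else np.zeros((0, 2)),
        as_arr(glut_epochs) if glut_epochs else np.zeros((0, 2)),
    )


def run(
    model: CircuitModel,
    duration: float,
    seed: int = 0,
    *,
    record_v: bool = True,
    stride: int = 1,
    perturbations=(),
    max_rate_hz: float = 600.0,
) -> SimulationResult:
    """Simulate ``model`` for ``duration`` ms.

    ``seed`` drives the per-step motor-command noise (when ``model.sigma_d`` is
    nonzero); structural randomness (weight noise, sensitivity scalings) is
    already frozen in the model.  Identical (model, seed, duration) inputs give
    bit-identical results.  Raises ``FloatingPointError`` on numerical blow-up.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = model.dt
    n_steps = int(round(duration / dt))
    n = model.n_neurons
    (
        params, drive, onset,
        g_pre, g_post, g_w, g_del,
        c_pre, c_post, c_w, c_del, c_erev, c_gly,
        m_pre, m_idx, m_w,
        n_cells, L,
    ) = _compile_arrays(model)
    sil_mask, sil_epochs, sil_gap_too, gly_epochs, glut_epochs = (
        _compile_perturbations(model, perturbations)
    )

    V = params[:, 5].copy()  # vr
    u = np.zeros(n)
    v_buf = np.tile(V, (L, 1))
    n_stored = n_steps // stride + 1
    v_out = (
        np.zeros((n_stored, n), dtype=np.float32)
        if record_v
        else np.zeros((1, n), dtype=np.float32)
    )
    v_out[0] = V
    musc_out = np.zeros((2 * n_cells, n_steps), dtype=np.float32)
    max_spikes = int(n * duration / 1000.0 * max_rate_hz) + 1000
    spike_t = np.zeros(max_spikes)
    spike_id = np.zeros(max_spikes, dtype=np.int64)

    noise_seed = int(seed) % (2**31 - 1)
    count = _kernel.step_loop(
        n_steps, dt,
        V, u,
        params[:, 0], params[:, 1], params[:, 2], params[:, 3],
        params[:, 4], params[:, 5], params[:, 6], params[:, 7], params[:, 8],
        drive, onset, float(model.sigma_d), noise_seed,
        g_pre, g_post, g_w, g_del, model.gap_mode,
        c_pre, c_post, c_w, c_del, c_erev, c_gly,
        model.tau_r, model.tau_f, model.v_thr, CHEM_OFF_MS,
        model.chem_sum_kernels,
        m_pre, m_idx, m_w,
        sil_mask, sil_epochs, sil_gap_too, gly_epochs, glut_epochs,
        v_buf, v_out, stride, musc_out, spike_t, spike_id,
    )
    if count < 0:
        raise FloatingPointError(
            f"membrane potential diverged at t = {-count * dt:.1f} ms "
            f"in model {model.name!r}"
        )
    if count > max_spikes:
        raise RuntimeError(
            f"spike buffer overflow ({count} spikes); raise max_rate_hz"
        )
    spikes = [spike_t[:count][spike_id[:count] == i] for i in range(n)]
    t_grid = np.arange(n_stored) * (dt * stride)
    return SimulationResult(
        model=model,
        duration=duration,
        dt=dt,
        stride=stride,
        seed=int(seed),
        t=t_grid,
        V=v_out if record_v else None,
        spikes=spikes,
        muscle_input=musc_out.reshape(2, n_cells, n_steps),
    )
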