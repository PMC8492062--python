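"""In-silico lesions: population silencing and transmitter blockade.

Silencing removes all synaptic and external currents delivered to every
member of a population (both sides) during the given epochs; the membrane
dynamics keep running on zero input, and outgoing synapses fall silent only
because the silenced neurons stop firing.  Transmitter blocks zero all
glycinergic or glutamatergic currents during the epochs; gap junctions and
neuromuscular transmission are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuits import CircuitModel
from .kinematics import (
    LocomotorSummary,
    detect_episodes,
    inter_episode_intervals,
    min_lr_crosscorr,
    tail_beat_frequencies,
)
from .musculoskeletal import body_kinematics

__all__ = [
    "PerturbationPlan",
    "apply_silencing",
    "apply_transmitter_block",
    "three_epoch_protocol",
]


@dataclass(frozen=True)
class PerturbationPlan:
    """A lesion schedule consumed by :func:`coilswim.engine.run`."""

    kind: str  # silence_population | block_glycine | block_glutamate
    target: str  # population name or transmitter class
    epochs: tuple[tuple[float, float], ...]
    include_gap: bool = True  # silencing also removes gap-junction input

    def __post_init__(self) -> None:
        if self.kind not in ("silence_population", "block_glycine", "block_glutamate"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        prev_end = -np.inf
        for start, end in self.epochs:
            if end <= start or start < prev_end:
                raise ValueError("epochs must be ordered and non-overlapping")
            prev_end = end


def apply_silencing(
    model: CircuitModel,
    population: str,
    window: tuple[float, float] | list[tuple[float, float]],
    include_gap: bool = True,
) -> PerturbationPlan:
    """Silence a named population during the window(s)."""
    kinds = {p.kind for p in model.populations}
    if population not in kinds:
        raise KeyError(
            f"population {population!r} not in model {model.name!r} (has {sorted(kinds)})"
        )
    epochs = _as_epochs(window)
    return PerturbationPlan("silence_population", population, epochs, include_gap)


def apply_transmitter_block(
    model: CircuitModel,
    transmitter: str,
    window: tuple[float, float] | list[tuple[float, float]],
) -> PerturbationPlan:
    """Block all glycinergic or glutamatergic currents during the window(s)."""
    if transmitter not in ("glycinergic", "glutamatergic", "glycine", "glutamate"):
        raise ValueError("transmitter must be glycine(rgic) or glutamate(rgic)")
    kind = "block_glycine" if transmitter.startswith("glyc") else "block_glutamate"
    del model  # blockade is model-independent
    return PerturbationPlan(kind, transmitter, _as_epochs(window))


def _as_epochs(window) -> tuple[tuple[float, float], ...]:
    if window and np.isscalar(window[0]):
        window = [tuple(window)]
    return tuple((float(a), float(b)) for a, b in window)


def _epoch_summary(kin, lo: float, hi: float, skip_ms: float) -> LocomotorSummary:
    """Swim statistics restricted to [lo, hi) ms of an existing kinematics."""
    episodes = [
        e for e in detect_episodes(kin.integrated, kin.dt, skip_ms=skip_ms)
        if lo <= e.start < hi
    ]
    intervals = [g for g in inter_episode_intervals(episodes)]
    freqs = []
    dt = kin.dt
    i0, i1 = int(lo / dt), int(hi / dt)
    sub = kin.tail_y[i0:i1]
    freqs = tail_beat_frequencies(sub, dt, skip_ms=skip_ms if lo == 0 else 0.0)
    n_cells = kin.VL.shape[0]
    lr = {}
    for somite in (5, min(10, n_cells)):
        lr[somite] = min_lr_crosscorr(
            kin.VL[somite - 1, i0:i1], kin.VR[somite - 1, i0:i1], dt,
            skip_ms=skip_ms if lo == 0 else 0.0,
        )
    return LocomotorSummary(
        episodes=episodes,
        intervals=intervals,
        tail_beat_freqs=freqs,
        min_crosscorr=lr,
    )


def three_epoch_protocol(
    model: CircuitModel,
    perturbation: PerturbationPlan | None,
    epoch_ms: float = 5000.0,
    seed: int = 0,
) -> list[LocomotorSummary]:
    """Run three consecutive epochs with the perturbation active in epoch 2.

    Returns one :class:`LocomotorSummary` per epoch (episodes, inter-episode
    intervals, tail-beat frequencies, and left-right alternation at somites 5
    and 10).  The first 200 ms of the run are excluded from epoch-1 analysis.
    """
    from .engine import run

    plans = ()
    if perturbation is not None:
        plan = PerturbationPlan(
            perturbation.kind,
            perturbation.target,
            ((epoch_ms, 2 * epoch_ms),),
            perturbation.include_gap,
        )
        plans = (plan,)
    result = run(model, 3 * epoch_ms, seed=seed, record_v=False, perturbations=plans)
    kin = body_kinematics(result)
    return [
        _epoch_summary(kin, e * epoch_ms, (e + 1) * epoch_ms,
                       skip_ms=200.0 if e == 0 else 0.0)
        for e in range(3)
    ]
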