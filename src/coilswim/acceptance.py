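"""Reference batteries reproducing the headline simulation results.

Each function rebuilds its model from the shipped parameter sheets, runs it
under the stated conditions, analyzes the locomotor output, and returns the
summary quantities: single-coiling frequency and coil duration, the
double-coiling coil-class percentages and double-coil duration from a noisy
five-run battery, and the beat-and-glide episode statistics from a ten-run
battery.  ``reproduce_reference_suite`` bundles them into one report.
"""

from __future__ import annotations

import numpy as np

from .circuits import build_beat_and_glide, build_double_coiling, build_single_coiling
from .engine import run
from .kinematics import (
    classify_coils,
    coil_chains,
    detect_episodes,
    inter_episode_intervals,
    tail_beat_frequencies,
)
from .musculoskeletal import body_kinematics
from .sensitivity import SensitivityConfig, randomize_model

__all__ = [
    "single_coiling_metrics",
    "double_coiling_battery",
    "beat_glide_battery",
    "reproduce_reference_suite",
]


def single_coiling_metrics(seed: int = 1, duration: float = 10000.0) -> dict:
    """Coiling frequency (Hz) and mean full-coil duration (ms) of the base model.

    The frequency counts full coil events over the simulated duration; the
    mean duration averages events not clipped by the analysis window.
    """
    model = build_single_coiling(rng=seed)
    result = run(model, duration, seed=seed, record_v=False)
    kin = body_kinematics(result)
    events, _ = classify_coils(kin.theta, kin.dt)
    full = [e for e in events if e.cls != "truncated"]
    durations = [e.duration for e in full if not e.censored]
    return {
        "coiling_freq_hz": 1000.0 * len(full) / duration,
        "mean_coil_duration_ms": float(np.mean(durations)) if durations else np.nan,
        "n_events": len(events),
        "events": events,
    }


def double_coiling_battery(
    seed: int = 1,
    n_runs: int = 5,
    duration: float = 100000.0,
    sigma_d: float = 0.5,
    sigma_p: float = 0.01,
    sigma_w: float = 0.05,
) -> dict:
    """Pooled coil-class percentages over noisy long runs of the double model.

    Matches the reference battery condition: Gaussian noise with sd 0.5 on the
    drive (per step), 0.01 on membrane parameters, and 0.05 on synaptic
    weights (frozen per run).
    """
    cfg = SensitivityConfig(sigma_d=sigma_d, sigma_p=sigma_p, sigma_w=sigma_w)
    counts = {"single": 0, "double": 0, "multiple": 0, "truncated": 0}
    double_durations: list[float] = []
    for r in range(n_runs):
        run_seed = (int(seed) + 7919 * r) % (2**31 - 1)
        rng = np.random.default_rng(run_seed)
        model = build_double_coiling(rng=rng)
        model = randomize_model(model, cfg, rng)
        try:
            result = run(model, duration, seed=run_seed, record_v=False)
        except FloatingPointError:
            continue  # a diverged run has no analyzable events
        kin = body_kinematics(result)
        events, _ = classify_coils(kin.theta, kin.dt)
        chains = coil_chains([e for e in events if e.cls != "truncated"])
        for chain in chains:
            cls = {1: "single", 2: "double"}.get(len(chain), "multiple")
            counts[cls] += 1
            if cls == "double" and not any(e.censored for e in chain):
                double_durations.append(chain[-1].offset - chain[0].onset)
        counts["truncated"] += sum(1 for e in events if e.cls == "truncated")
    total = sum(counts.values())
    pct = {k: 100.0 * v / total if total else np.nan for k, v in counts.items()}
    return {
        "pct": pct,
        "n_events": total,
        "mean_double_duration_ms": (
            float(np.mean(double_durations)) if double_durations else np.nan
        ),
    }


def beat_glide_battery(
    seed: int = 1, n_runs: int = 10, duration: float = 10000.0
) -> dict:
    """Grand-mean episode statistics over repeated base beat-and-glide runs."""
    durations: list[float] = []
    intervals: list[float] = []
    freqs: list[float] = []
    for r in range(n_runs):
        run_seed = (int(seed) + 7919 * r) % (2**31 - 1)
        model = build_beat_and_glide("base", rng=np.random.default_rng(run_seed))
        try:
            result = run(model, duration, seed=run_seed, record_v=False)
        except FloatingPointError:
            continue  # a diverged run has no analyzable events
        kin = body_kinematics(result)
        episodes = detect_episodes(kin.integrated, kin.dt)
        durations += [e.duration for e in episodes]
        intervals += inter_episode_intervals(episodes)
        freqs += tail_beat_frequencies(kin.tail_y, kin.dt)
    return {
        "mean_episode_duration_ms": float(np.mean(durations)) if durations else np.nan,
        "mean_inter_episode_interval_ms": (
            float(np.mean(intervals)) if intervals else np.nan
        ),
        "mean_tail_beat_freq_hz": float(np.mean(freqs)) if freqs else np.nan,
        "n_episodes": len(durations),
        "tail_beat_freqs": freqs,
    }


def reproduce_reference_suite(seed: int = 1, scale: float = 1.0) -> dict:
    """Run the full reference battery; ``scale`` < 1 shortens every run."""
    sc = single_coiling_metrics(seed, duration=10000.0)
    dc = double_coiling_battery(
        seed, n_runs=max(1, round(5 * scale)), duration=100000.0 * max(scale, 0.1)
    )
    bg = beat_glide_battery(seed, n_runs=max(2, round(10 * scale)))
    return {
        "single_coiling": {k: v for k, v in sc.items() if k != "events"},
        "double_coiling": dc,
        "beat_and_glide": {
            k: v for k, v in bg.items() if k != "tail_beat_freqs"
        },
    }
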