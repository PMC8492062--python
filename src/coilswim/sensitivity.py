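"""Gaussian parameter-noise sensitivity batteries.

Robustness of each model is probed by scaling one set of parameters with
multiplicative Gaussian noise (mean 1): the tonic motor-command amplitude
(sigma_d, redrawn every time step), the rostrocaudal extent of axonal
projections (sigma_l), the membrane-dynamics parameters (sigma_p), or the
synaptic weights (sigma_w; chemical-only and gap-only variants).  Structural
noise is drawn once at the start of each simulation and frozen; drive noise
varies step by step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import GAP, CircuitModel, MODEL_FACTORIES
from .kinematics import (
    classify_coils,
    detect_episodes,
    inter_episode_intervals,
    min_lr_crosscorr,
    tail_beat_frequencies,
)
from .musculoskeletal import body_kinematics

__all__ = ["SensitivityConfig", "randomize_model", "run_battery"]


@dataclass(frozen=True)
class SensitivityConfig:
    """Noise levels (Gaussian sd of the scale factors) for one battery run.

    The sensitivity batteries vary exactly one sigma at a time; the base
    double-coiling condition, which combines small sigma_d/sigma_p/sigma_w
    levels, is expressed with several nonzero fields.
    """

    sigma_d: float = 0.0
    sigma_l: float = 0.0
    sigma_p: float = 0.0
    sigma_w: float = 0.0
    sigma_w_chem: float = 0.0
    sigma_w_gap: float = 0.0
    n_runs: int = 10
    duration: float = 20000.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_d", "sigma_l", "sigma_p", "sigma_w",
                     "sigma_w_chem", "sigma_w_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def randomize_model(
    model: CircuitModel, config: SensitivityConfig, rng: np.random.Generator
) -> CircuitModel:
    """Apply frozen structural noise to a model copy.

    sigma_l rebuilds the model from its factory with per-neuron scaled
    projection extents (delays and target sets re-derived); sigma_w variants
    scale connection weights once (clamped at 0); sigma_p scales every
    membrane parameter of every neuron once (left signed).  sigma_d is stored
    on the model and applied per step inside the engine.
    """
    if config.sigma_l > 0:
        factory = MODEL_FACTORIES[model.name]
        kwargs = {
            k: v for k, v in model.factory_kwargs.items() if k != "variant"
        }
        model = factory(rng=rng, sigma_l=config.sigma_l, **kwargs)
    else:
        model = model.copy()

    def scale_weights(conns, sd):
        for c in conns:
            c.weight = max(0.0, c.weight * (1.0 + sd * rng.standard_normal()))

    if config.sigma_w > 0:
        scale_weights(model.connections, config.sigma_w)
        scale_weights(model.muscle_synapses, config.sigma_w)
    if config.sigma_w_chem > 0:
        chem = [c for c in model.connections if c.kind != GAP]
        scale_weights(chem, config.sigma_w_chem)
        scale_weights(model.muscle_synapses, config.sigma_w_chem)
    if config.sigma_w_gap > 0:
        gaps = [c for c in model.connections if c.kind == GAP]
        scale_weights(gaps, config.sigma_w_gap)

    if config.sigma_p > 0:
        model.param_scales = 1.0 + config.sigma_p * rng.standard_normal(
            (model.n_neurons, 9)
        )
    model.sigma_d = config.sigma_d
    return model


def _coiling_metrics(kin, duration_ms: float) -> dict:
    events, props = classify_coils(kin.theta, kin.dt)
    full = [e for e in events if e.cls != "truncated"]
    return {
        "coiling_freq_hz": 1000.0 * len(full) / duration_ms,
        "prop_full_coils": len(full) / len(events) if events else np.nan,
        "prop_single": props["single"],
        "prop_double": props["double"],
        "prop_multiple": props["multiple"],
        "prop_truncated": props["truncated"],
    }


def _swim_metrics(kin) -> dict:
    episodes = detect_episodes(kin.integrated, kin.dt)
    intervals = inter_episode_intervals(episodes)
    freqs = tail_beat_frequencies(kin.tail_y, kin.dt)
    lr = min_lr_crosscorr(kin.VL.sum(axis=0), kin.VR.sum(axis=0), kin.dt)
    return {
        "episode_duration_ms": float(np.mean([e.duration for e in episodes]))
        if episodes else np.nan,
        "inter_episode_interval_ms": float(np.mean(intervals))
        if intervals else np.nan,
        "tail_beat_freq_hz": float(np.mean(freqs)) if freqs else np.nan,
        "min_lr_crosscorr": lr,
        "n_episodes": len(episodes),
    }


def run_battery(
    model_name: str,
    sigma_name: str,
    grid,
    n_runs: int = 10,
    duration: float = 20000.0,
    base_seed: int = 0,
    factory_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run ``n_runs`` seeds at every sigma value; one tidy row per run.

    ``sigma_name`` is one of d, l, p, w, w_chem, w_gap.  Coiling models report
    coiling frequency and coil-class proportions; the swimming models report
    episode statistics, tail-beat frequency, and left-right alternation.
    """
    from .engine import run

    if sigma_name not in ("d", "l", "p", "w", "w_chem", "w_gap"):
        raise ValueError(f"unknown sigma name {sigma_name!r}")
    factory = MODEL_FACTORIES[model_name]
    coiling = "coiling" in model_name
    rows = []
    for gi, sigma in enumerate(grid):
        for r in range(n_runs):
            seed = (int(base_seed) + 7919 * gi + r) % (2**31 - 1)
            rng = np.random.default_rng(seed)
            cfg = SensitivityConfig(
                **{f"sigma_{sigma_name}": float(sigma)},
                n_runs=n_runs,
                duration=duration,
                base_seed=base_seed,
            )
            model = factory(**(factory_kwargs or {}), rng=rng)
            model = randomize_model(model, cfg, rng)
            result = run(model, duration, seed=seed, record_v=False)
            kin = body_kinematics(result)
            metrics = (
                _coiling_metrics(kin, duration) if coiling else _swim_metrics(kin)
            )
            rows.append(
                {"sigma_name": sigma_name, "sigma": float(sigma), "seed": seed,
                 **metrics}
            )
    return pd.DataFrame(rows)
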