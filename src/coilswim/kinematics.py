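"""Analysis of locomotor output: episodes, tail beats, coils, phase relations.

All analyses ignore the first 200 ms of a simulation, where initial-condition
transients live.  Episode detection thresholds the boxcar-smoothed integrated
motor output at 0.5 arbitrary units; tail-beat frequency is the reciprocal of
intervals between successive same-direction midline crossings of the most
caudal body point; left-right alternation is the minimum of the normalized
(non-mean-subtracted) cross-correlation of left and right muscle activity
over short lags.  Coil events are detected on the body-angle field and
classified as parts of single, double, or multiple coilings, or as truncated
(rostral-only) contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate, correlation_lags, find_peaks

ANALYSIS_SKIP_MS = 200.0

__all__ = [
    "Episode",
    "CoilEvent",
    "LocomotorSummary",
    "detect_episodes",
    "inter_episode_intervals",
    "tail_beat_frequencies",
    "min_lr_crosscorr",
    "phase_delay",
    "classify_coils",
]


@dataclass(frozen=True)
class Episode:
    """One suprathreshold bout of integrated motor output."""

    start: float  # ms
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CoilEvent:
    """One unilateral coil: a maximal interval of large same-side body bend."""

    side: str  # left | right
    onset: float  # ms
    offset: float
    max_abs_theta: float  # rad
    caudal_reach: float  # fraction of segments exceeding the threshold
    cls: str = "unclassified"  # single | double | multiple | truncated
    censored: bool = False  # clipped by the analysis window; duration unreliable

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class LocomotorSummary:
    """Summary statistics of one run (coiling or swimming)."""

    episodes: list[Episode] = field(default_factory=list)
    intervals: list[float] = field(default_factory=list)  # ms
    tail_beat_freqs: list[float] = field(default_factory=list)  # Hz
    coil_events: list[CoilEvent] = field(default_factory=list)
    coil_proportions: dict[str, float] = field(default_factory=dict)
    min_crosscorr: dict[int, float] = field(default_factory=dict)  # somite -> coeff

    def mean_episode_duration(self) -> float:
        return float(np.mean([e.duration for e in self.episodes])) if self.episodes else np.nan

    def mean_interval(self) -> float:
        return float(np.mean(self.intervals)) if self.intervals else np.nan

    def mean_tail_beat_freq(self) -> float:
        return float(np.mean(self.tail_beat_freqs)) if self.tail_beat_freqs else np.nan


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.where(padded == 1)[0]
    stops = np.where(padded == -1)[0]
    return list(zip(starts, stops))


def detect_episodes(
    trace: np.ndarray,
    dt: float,
    threshold: float = 0.5,
    skip_ms: float = ANALYSIS_SKIP_MS,
) -> list[Episode]:
    """Maximal intervals where the smoothed motor output is >= threshold."""
    trace = np.asarray(trace)
    first = int(round(skip_ms / dt))
    mask = trace >= threshold
    mask[:first] = False
    return [Episode(start=s * dt, end=e * dt) for s, e in _runs(mask)]


def inter_episode_intervals(episodes: list[Episode]) -> list[float]:
    """Gaps (ms) between consecutive episodes."""
    return [b.start - a.end for a, b in zip(episodes, episodes[1:])]


def tail_beat_frequencies(
    trace: np.ndarray,
    dt: float,
    crossing_threshold: float = 0.5,
    max_interval_ms: float = 100.0,
    skip_ms: float = ANALYSIS_SKIP_MS,
    per_half_cycle: bool = True,
) -> list[float]:
    """Instantaneous tail-beat frequencies (Hz) from midline crossings.

    A crossing is detected when the lateral tail displacement moves from one
    side beyond ``crossing_threshold`` on the other side (hysteresis about the
    midline).  Each beat is one crossing to the other side (a left-to-right or
    right-to-left flick); the instantaneous frequency is the reciprocal of the
    interval between consecutive crossings.  With ``per_half_cycle=False`` the
    interval is instead measured between consecutive same-direction crossings
    (one full undulation cycle).  Intervals longer than ``max_interval_ms``
    fall between swim episodes and are discarded.
    """
    trace = np.asarray(trace, dtype=float)
    first = int(round(skip_ms / dt))
    state = 0
    crossings: list[tuple[float, int]] = []
    for i in range(first, len(trace)):
        v = trace[i]
        if v > crossing_threshold and state != 1:
            if state == -1:
                crossings.append((i * dt, 1))
            state = 1
        elif v < -crossing_threshold and state != -1:
            if state == 1:
                crossings.append((i * dt, -1))
            state = -1
    freqs = []
    if per_half_cycle:
        times = [t for t, _ in crossings]
        for t1, t2 in zip(times, times[1:]):
            if t2 - t1 <= max_interval_ms:
                freqs.append(1000.0 / (t2 - t1))
    else:
        for direction in (1, -1):
            times = [t for t, d in crossings if d == direction]
            for t1, t2 in zip(times, times[1:]):
                if t2 - t1 <= max_interval_ms:
                    freqs.append(1000.0 / (t2 - t1))
    return freqs


def min_lr_crosscorr(
    vl: np.ndarray,
    vr: np.ndarray,
    dt: float,
    lag_ms: float = 10.0,
    skip_ms: float = ANALYSIS_SKIP_MS,
) -> float:
    """Minimum normalized left-right cross-correlation over lags in +/- lag_ms.

    The coefficient is not mean-subtracted: 0 means out-of-phase alternation
    of non-negative activity, 1 means in-phase synchrony.  Returns NaN when a
    side carries no activity (undefined alternation).
    """
    first = int(round(skip_ms / dt))
    vl = np.asarray(vl, dtype=float)[first:]
    vr = np.asarray(vr, dtype=float)[first:]
    el, er = np.dot(vl, vl), np.dot(vr, vr)
    if el == 0.0 or er == 0.0:
        return float("nan")
    max_lag = int(round(lag_ms / dt))
    norm = np.sqrt(el * er)
    coeffs = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            c = np.dot(vl[: len(vl) - lag], vr[lag:])
        else:
            c = np.dot(vl[-lag:], vr[: len(vr) + lag])
        coeffs.append(c / norm)
    return float(np.min(coeffs))


def phase_delay(
    ref: np.ndarray,
    test: np.ndarray,
    dt: float,
    period_override_ms: float | None = None,
    skip_ms: float = ANALYSIS_SKIP_MS,
) -> float:
    """Phase (rad) of ``test`` relative to ``ref``.

    The cycle period is the lag of the first autocorrelation peak of the
    reference trace (or ``period_override_ms``, used for the coiling models
    where the long inter-coil interval would otherwise dominate).  The phase
    is ``2 pi * delay / period`` with the cross-correlation peak lag ``delay``
    signed so that a negative phase means the reference precedes the test.
    Returns NaN when no period can be estimated and no override is given.
    """
    first = int(round(skip_ms / dt))
    ref = np.asarray(ref, dtype=float)[first:]
    test = np.asarray(test, dtype=float)[first:]
    ref = ref - ref.mean()
    test = test - test.mean()
    if period_override_ms is not None:
        period = period_override_ms
    else:
        ac = correlate(ref, ref, mode="full")
        mid = len(ac) // 2
        pos = ac[mid + 1 :]
        peaks, _ = find_peaks(pos)
        if len(peaks) == 0:
            return float("nan")
        period = (peaks[np.argmax(pos[peaks])] + 1) * dt
    cc = correlate(test, ref, mode="full")
    lags = correlation_lags(len(test), len(ref), mode="full")
    half = int(round(period / dt / 2))
    window = np.abs(lags) <= half
    # peak at positive lag = test follows ref; phase negative when ref precedes
    peak_lag = lags[window][np.argmax(cc[window])] * dt
    return float(-2.0 * np.pi * peak_lag / period)


def classify_coils(
    theta: np.ndarray,
    dt: float,
    amplitude_threshold: float = 0.5,
    caudal_fraction: float = 2.0 / 3.0,
    pairing_window_ms: float = 1000.0,
    min_duration_ms: float = 100.0,
    skip_ms: float = ANALYSIS_SKIP_MS,
) -> tuple[list[CoilEvent], dict[str, float]]:
    """Detect and classify coil events on a (segments, time) body-angle field.

    A coil candidate is a maximal interval of constant bending side where the
    largest |angle| across segments exceeds ``amplitude_threshold`` (rad).  A
    candidate is a full coil when at least ``caudal_fraction`` of the segments
    exceed the threshold during the event, otherwise a truncated (rostral)
    contraction.  Consecutive opposite-side full coils whose onsets are within
    ``pairing_window_ms`` chain into double (2) or multiple (>= 3) coilings.
    Proportions are per event (a double coiling is one event of two coils).
    """
    theta = np.asarray(theta, dtype=float)
    n_seg, n_t = theta.shape
    first = int(round(skip_ms / dt))
    amp = np.abs(theta).max(axis=0)
    lead_seg = np.abs(theta).argmax(axis=0)
    side_sign = np.sign(theta[lead_seg, np.arange(n_t)])
    mask = amp >= amplitude_threshold
    mask[:first] = False

    events: list[CoilEvent] = []
    min_samples = int(round(min_duration_ms / dt))
    for s, e in _runs(mask):
        # split the run wherever the bending side flips
        seg_start = s
        for i in range(s + 1, e + 1):
            if i == e or side_sign[i] != side_sign[seg_start]:
                if i - seg_start < min_samples:
                    seg_start = i
                    continue
                window = theta[:, seg_start:i]
                reach = float(
                    np.mean(np.abs(window).max(axis=1) >= amplitude_threshold)
                )
                events.append(
                    CoilEvent(
                        side="right" if side_sign[seg_start] > 0 else "left",
                        onset=seg_start * dt,
                        offset=i * dt,
                        max_abs_theta=float(np.abs(window).max()),
                        caudal_reach=reach,
                        cls="full" if reach >= caudal_fraction else "truncated",
                        censored=(seg_start <= first or i >= n_t - 1),
                    )
                )
                seg_start = i

    # chain consecutive opposite-side full coils into double/multiple events
    chains = coil_chains(
        [ev for ev in events if ev.cls == "full"], pairing_window_ms
    )
    for chain in chains:
        cls = {1: "single", 2: "double"}.get(len(chain), "multiple")
        for ev in chain:
            ev.cls = cls

    n_events = len(chains) + sum(1 for ev in events if ev.cls == "truncated")
    proportions = {k: 0.0 for k in ("single", "double", "multiple", "truncated")}
    if n_events:
        for chain in chains:
            proportions[{1: "single", 2: "double"}.get(len(chain), "multiple")] += 1
        proportions["truncated"] += sum(1 for ev in events if ev.cls == "truncated")
        for k in proportions:
            proportions[k] /= n_events
    return events, proportions


def coil_chains(
    full_events: list[CoilEvent], pairing_window_ms: float = 1000.0
) -> list[list[CoilEvent]]:
    """Chain non-truncated coils: consecutive opposite-side coils whose onsets
    fall within the pairing window belong to one locomotor event."""
    chains: list[list[CoilEvent]] = []
    for ev in sorted(full_events, key=lambda e: e.onset):
        if (
            chains
            and ev.side != chains[-1][-1].side
            and ev.onset - chains[-1][-1].onset <= pairing_window_ms
        ):
            chains[-1].append(ev)
        else:
            chains.append([ev])
    return chains
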