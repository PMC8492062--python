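"""Locomotor analysis: episodes, tail beats, alternation, phase, coil classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coilswim.kinematics import (
    Episode,
    classify_coils,
    coil_chains,
    detect_episodes,
    inter_episode_intervals,
    min_lr_crosscorr,
    phase_delay,
    tail_beat_frequencies,
)

DT = 0.1


def boxcar_trace(windows, total_ms=5000.0, amplitude=1.0):
    t = np.arange(0, total_ms, DT)
    out = np.zeros_like(t)
    for a, b in windows:
        out[(t >= a) & (t < b)] = amplitude
    return out


class TestEpisodes:
    def test_no_episodes_on_silence(self):
        assert detect_episodes(np.zeros(10000), DT) == []

    def test_synthetic_boxcar_detected(self):
        trace = boxcar_trace([(1000.0, 1250.0)])
        (ep,) = detect_episodes(trace, DT)
        assert ep.start == pytest.approx(1000.0, abs=DT)
        assert ep.duration == pytest.approx(250.0, abs=2 * DT)

    def test_initial_transient_excluded(self):
        trace = boxcar_trace([(50.0, 150.0), (1000.0, 1100.0)])
        eps = detect_episodes(trace, DT)
        assert len(eps) == 1 and eps[0].start >= 200.0

    def test_durations_and_gaps_tile_the_active_span(self):
        windows = [(500.0, 800.0), (1200.0, 1500.0), (2000.0, 2600.0)]
        eps = detect_episodes(boxcar_trace(windows), DT)
        gaps = inter_episode_intervals(eps)
        span = eps[-1].end - eps[0].start
        total = sum(e.duration for e in eps) + sum(gaps)
        assert total == pytest.approx(span)
        assert all(g > 0 for g in gaps)
        assert all(b.start > a.end for a, b in zip(eps, eps[1:]))


class TestTailBeats:
    def sinusoid(self, freq_hz, total_ms=2000.0, amp=1.0):
        t = np.arange(0.0, total_ms, DT)
        return amp * np.sin(2 * np.pi * freq_hz * t / 1000.0)

    def test_pure_sinusoid_frequencies(self):
        trace = self.sinusoid(30.0)
        full = tail_beat_frequencies(trace, DT, per_half_cycle=False)
        assert np.allclose(full, 30.0, atol=0.5)
        half = tail_beat_frequencies(trace, DT)  # each flick counted
        assert np.allclose(half, 60.0, atol=1.0)

    def test_long_intervals_discarded(self):
        # alternating flicks 150 ms apart: all intervals exceed the 100 ms cap
        t = np.arange(0.0, 3000.0, DT)
        trace = np.zeros_like(t)
        sign = 1.0
        for onset in np.arange(300.0, 2900.0, 150.0):
            trace[(t >= onset) & (t < onset + 10.0)] = sign
            sign = -sign
        assert tail_beat_frequencies(trace, DT) == []

    def test_flat_trace_has_no_beats(self):
        assert tail_beat_frequencies(np.zeros(10000), DT) == []

    def test_invariant_to_amplitude_scaling(self):
        trace = self.sinusoid(25.0)
        a = tail_beat_frequencies(trace, DT)
        b = tail_beat_frequencies(2.0 * trace, DT)
        assert len(a) == len(b)
        np.testing.assert_allclose(a, b, rtol=0.02)


class TestLeftRightAlternation:
    def test_identical_constant_signals_give_unity(self):
        v = np.ones(20000)
        assert min_lr_crosscorr(v, v, DT) == pytest.approx(1.0, abs=0.01)

    def test_non_overlapping_half_waves_give_near_zero(self):
        t = np.arange(0.0, 2000.0, DT)
        phase = 2 * np.pi * 20.0 * t / 1000.0
        vl = np.maximum(np.sin(phase), 0.0)
        vr = np.maximum(-np.sin(phase), 0.0)
        assert min_lr_crosscorr(vl, vr, DT) < 0.05

    def test_silent_side_is_undefined(self):
        v = np.abs(np.sin(np.arange(0, 1000, DT)))
        assert np.isnan(min_lr_crosscorr(v, np.zeros_like(v), DT))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetric_in_left_and_right(self, seed):
        rng = np.random.default_rng(seed)
        vl = rng.random(4000)
        vr = rng.random(4000)
        assert min_lr_crosscorr(vl, vr, DT) == pytest.approx(
            min_lr_crosscorr(vr, vl, DT), abs=1e-12
        )


class TestPhaseDelay:
    def sin(self, shift_ms=0.0, period_ms=100.0):
        t = np.arange(0.0, 3000.0, DT)
        return np.sin(2 * np.pi * (t - shift_ms) / period_ms)

    def test_self_phase_is_zero(self):
        ref = self.sin()
        assert phase_delay(ref, ref, DT) == pytest.approx(0.0, abs=1e-6)

    def test_quarter_period_shift(self):
        phase = phase_delay(self.sin(), self.sin(shift_ms=25.0), DT)
        assert abs(phase) == pytest.approx(np.pi / 2, rel=0.05)

    def test_antiphase_is_pi(self):
        phase = phase_delay(self.sin(), -self.sin(), DT)
        assert abs(phase) == pytest.approx(np.pi, rel=0.05)

    def test_period_override_used_for_sparse_events(self):
        phase = phase_delay(
            self.sin(), self.sin(shift_ms=25.0), DT, period_override_ms=100.0
        )
        assert abs(phase) == pytest.approx(np.pi / 2, rel=0.05)

    def test_aperiodic_trace_flagged(self):
        rng = np.random.default_rng(0)
        flat = np.zeros(5000)
        assert np.isnan(phase_delay(flat, rng.random(5000), DT))


def synthetic_theta(events, n_seg=10, total_ms=8000.0, caudal_fraction=1.0):
    """Build a (segments, time) angle field from (onset, offset, side, amp)."""
    t = np.arange(0.0, total_ms, DT)
    theta = np.zeros((n_seg, len(t)))
    reach = max(1, int(round(caudal_fraction * n_seg)))
    for onset, offset, side, amp in events:
        mask = (t >= onset) & (t < offset)
        bump = amp * np.sin(np.pi * (t[mask] - onset) / (offset - onset))
        sign = 1.0 if side == "right" else -1.0
        theta[:reach, mask] += sign * bump
    return theta


class TestCoilClassification:
    def test_isolated_full_coils_are_singles(self):
        theta = synthetic_theta(
            [(1000, 2000, "left", 1.2), (4000, 5000, "left", 1.2)]
        )
        events, props = classify_coils(theta, DT)
        assert [e.cls for e in events] == ["single", "single"]
        assert props["single"] == 1.0

    def test_opposite_side_pair_chains_into_double(self):
        theta = synthetic_theta(
            [(1000, 1900, "left", 1.2), (1950, 2800, "right", 1.2)]
        )
        events, props = classify_coils(theta, DT)
        assert [e.cls for e in events] == ["double", "double"]
        assert props == {"single": 0.0, "double": 1.0, "multiple": 0.0,
                         "truncated": 0.0}

    def test_three_alternating_coils_are_multiple(self):
        theta = synthetic_theta(
            [(1000, 1800, "left", 1.2), (1900, 2700, "right", 1.2),
             (2800, 3600, "left", 1.2)]
        )
        events, _ = classify_coils(theta, DT)
        assert {e.cls for e in events} == {"multiple"}

    def test_distant_opposite_coils_stay_single(self):
        theta = synthetic_theta(
            [(1000, 1900, "left", 1.2), (4000, 4900, "right", 1.2)]
        )
        events, _ = classify_coils(theta, DT)
        assert [e.cls for e in events] == ["single", "single"]

    def test_rostral_only_contraction_is_truncated(self):
        theta = synthetic_theta(
            [(1000, 2000, "left", 1.2)], caudal_fraction=0.3
        )
        events, props = classify_coils(theta, DT)
        assert [e.cls for e in events] == ["truncated"]
        assert events[0].caudal_reach < 2.0 / 3.0
        assert props["truncated"] == 1.0

    def test_subthreshold_wiggles_ignored(self):
        theta = synthetic_theta([(1000, 2000, "left", 0.3)])
        events, props = classify_coils(theta, DT)
        assert events == []
        assert sum(props.values()) == 0.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_proportions_sum_to_one_over_detected_events(self, seed):
        rng = np.random.default_rng(seed)
        events = []
        t0 = 500.0
        for _ in range(rng.integers(1, 8)):
            dur = rng.uniform(300, 900)
            side = rng.choice(["left", "right"])
            events.append((t0, t0 + dur, side, rng.uniform(0.6, 1.5)))
            t0 += dur + rng.uniform(100, 2000)
        theta = synthetic_theta(events, total_ms=t0 + 1000)
        found, props = classify_coils(theta, DT)
        if found:
            assert sum(props.values()) == pytest.approx(1.0)
        chains = coil_chains([e for e in found if e.cls != "truncated"])
        assert sum(len(c) for c in chains) == sum(
            1 for e in found if e.cls != "truncated"
        )

    def test_episode_invariants(self):
        ep = Episode(start=100.0, end=300.0)
        assert ep.duration == 200.0
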