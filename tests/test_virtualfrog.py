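"""Virtual gap-detection caller: oscillator limits, response structure,
elaboration dynamics, state invariants."""

import numpy as np
import pytest

from chorusloop import (Condition, FrogParams, VirtualFrog, build_call_bank,
                        enumerate_conditions, simulate_alternation,
                        simulate_presentations)
from chorusloop.inhibition import frames_from_waveform


@pytest.fixture()
def frog():
    return VirtualFrog(FrogParams(), rng=np.random.default_rng(0))


class TestOscillator:
    def test_free_running_zero_noise_intervals_exact(self):
        f = VirtualFrog(FrogParams.pure_oscillator(noise_sd=0.0),
                        rng=np.random.default_rng(1))
        events = f.run_silence(20.0)
        intervals = np.diff([e.time for e in events])
        assert np.allclose(intervals, 1.71, atol=1e-12)

    def test_pure_oscillator_prc_flat_beyond_refractory(self, library):
        """With all gains off the stimulus cannot perturb call timing."""
        track = frames_from_waveform(
            library.presentation("highOP", "silence").waveform)
        periods = {}
        for delay in (0.6, 1.0, 1.4):
            f = VirtualFrog(FrogParams.pure_oscillator(noise_sd=0.0),
                            rng=np.random.default_rng(2))
            f.reset(0.0)
            ev = f.run_silence(delay)
            ev += f.run_frames(track, delay)
            ev += f.run_silence(delay + 4.0)
            periods[delay] = ev[0].time
        assert np.allclose(list(periods.values()), 1.71, atol=1e-12)

    def test_period_noise_spreads_intervals(self):
        f = VirtualFrog(FrogParams.pure_oscillator(noise_sd=0.12),
                        rng=np.random.default_rng(3))
        intervals = np.diff([e.time for e in f.run_silence(60.0)])
        assert 0.05 < np.std(intervals) < 0.25

    def test_unstimulated_frog_eventually_falls_silent(self):
        f = VirtualFrog(FrogParams(), rng=np.random.default_rng(4))
        events = f.run_silence(120.0)
        assert len(events) > 0
        assert events[-1].time < 60.0  # arousal decay silences it


class TestResponses:
    def test_isolated_stimuli_almost_never_overlapped(self):
        conds = [c for c in enumerate_conditions()
                 if c.motif_kind == "silence"]
        df = simulate_presentations(conds, reps=10, params=FrogParams(),
                                    seed=5)
        assert df.overlapped.mean() < 0.07

    def test_overlap_sync_motif_raises_overlap_at_late_delay(self):
        conds = [Condition("highOP", 1.5, "silence"),
                 Condition("highOP", 1.5, "overlap_sync")]
        df = simulate_presentations(conds, reps=120, params=FrogParams(),
                                    seed=6)
        rates = df.groupby("motif_kind").overlapped.mean()
        assert rates["overlap_sync"] > rates["silence"]
        assert rates["overlap_sync"] > 0.2

    def test_response_delay_mode_near_min_latency_after_offset(self):
        """After conspecific motifs, responses cluster shortly after the
        stimulus offset."""
        conds = [Condition("lowOP", d, "overlap_sync") for d in (1.2, 1.5)]
        df = simulate_presentations(conds, reps=80, params=FrogParams(),
                                    seed=7)
        ok = df[df.response_delay.notna() & ~df.spontaneous]
        post_offset = ok.response_delay - 0.428
        frac_short = ((post_offset > 0) & (post_offset < 0.15)).mean()
        assert frac_short > 0.3

    def test_alternation_median_period_near_dyadic_value(self):
        periods = simulate_alternation(250, FrogParams(), seed=8)
        assert len(periods) >= 200
        assert abs(np.median(periods) - 1.71) < 0.06

    def test_state_levels_stay_nonnegative(self, frog, library):
        track = frames_from_waveform(
            library.presentation("intOP", "overlapping").waveform)
        frog.reset(0.0)
        hop = track.hop
        for i in range(len(track)):
            frog.step((track.intensity[i], track.inhibition[i],
                       track.conspecific[i]), hop)
            s = frog.state
            assert s.stim_generic >= 0 and s.stim_conspecific >= 0
            assert s.arousal >= 0 and s.elaboration >= 0

    def test_min_latency_respected(self, library):
        """No triggered response arrives sooner than min_latency after any
        acoustic feature (frame) of the stimulus."""
        track = frames_from_waveform(
            library.presentation("highOP", "overlap_sync").waveform)
        lead = library.presentation("highOP", "overlap_sync").lead
        p = FrogParams(min_latency=0.06)
        for seed in range(10):
            f = VirtualFrog(p, rng=np.random.default_rng(seed))
            f.reset(0.0)
            t0 = 1.5 - lead
            ev = f.run_silence(t0)
            start = f.state.t
            ev = f.run_frames(track, t0)
            for e in ev:
                assert e.time >= start + 0.06 - 1e-9


class TestElaboration:
    def test_inertia_one_keeps_elaboration_constant(self, library):
        p = FrogParams(elaboration_inertia=1.0, elaboration_init=0.7)
        f = VirtualFrog(p, rng=np.random.default_rng(9))
        track = frames_from_waveform(
            library.presentation("highOP", "overlap_sync").waveform)
        t = 0.0
        scores = []
        for _ in range(10):
            ev = f.run_frames(track, t)
            ev += f.run_silence(f.state.t + 1.0)
            scores += [e.elaboration for e in ev]
            t = f.state.t
        assert np.allclose(scores, 0.7, atol=1e-12)

    def test_sustained_stimulation_raises_elaboration(self, library):
        p = FrogParams(elaboration_init=0.2, arousal_init=0.3)
        f = VirtualFrog(p, rng=np.random.default_rng(10))
        track = frames_from_waveform(
            library.presentation("highOP", "overlap_sync").waveform)
        scores, t = [], 0.0
        for _ in range(20):
            ev = f.run_frames(track, t)
            ev += f.run_silence(f.state.t + 1.0)
            scores += [e.elaboration for e in ev]
            t = f.state.t
        assert np.mean(scores[-5:]) > np.mean(scores[:5])

    def test_long_silence_lowers_elaboration(self):
        f = VirtualFrog(FrogParams(), rng=np.random.default_rng(11))
        scores = [e.elaboration for e in f.run_silence(22.0)]
        assert len(scores) >= 6
        assert np.mean(scores[-3:]) < np.mean(scores[:3])

    def test_emit_call_draws_nearest_elaboration_level(self, frog):
        bank = build_call_bank(8000)
        frog.state.elaboration = 0.93
        wav, score = frog.emit_call(bank)
        scores = [s for s, _ in bank]
        nearest = min(scores, key=lambda s: abs(s - 0.93))
        assert len(wav.meta["chucks"]) == scores.index(nearest)
        assert score == pytest.approx(0.93)

    def test_empty_bank_rejected(self, frog):
        with pytest.raises(ValueError):
            frog.emit_call([])


class TestParams:
    def test_invariant_ordering_enforced(self):
        with pytest.raises(ValueError):
            FrogParams(min_latency=0.5, refractory=0.45)

    def test_yaml_round_trip(self, tmp_path):
        p = FrogParams(median_period=1.8, seed=42)
        path = tmp_path / "frog.yaml"
        p.to_yaml(path)
        assert FrogParams.from_yaml(path) == p
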