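"""Response metrics: delay arithmetic, overlap classification, elaboration
scoring, standardization, offline extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chorusloop import (CallSpec, Condition, EngineConfig,
                        Waveform, classify_overlap_interval,
                        compute_delays, elaboration_score, extract_onsets,
                        randomize_plan, records_to_frame,
                        run_simulated_session, standardize, synth_call)
from chorusloop.respmetrics import AlignmentError


class TestOverlapClassification:
    def test_onset_during_second_chuck_is_unrestricted_overlap(self):
        # two-chuck call, 0.519 s, first chuck ends 0.449 s in
        ov, rov = classify_overlap_interval(R=10.0 + 0.9 * 0.519, S=10.0,
                                            stimulus_duration=0.519,
                                            first_chuck_end=0.449)
        assert ov and not rov

    def test_onset_at_exact_offset_is_alternation(self):
        ov, rov = classify_overlap_interval(R=10.519, S=10.0,
                                            stimulus_duration=0.519,
                                            first_chuck_end=0.449)
        assert not ov and not rov

    def test_onset_during_whine_is_both(self):
        ov, rov = classify_overlap_interval(R=10.1, S=10.0,
                                            stimulus_duration=0.519,
                                            first_chuck_end=0.449)
        assert ov and rov

    def test_single_chuck_restricted_equals_overlapped(self):
        for R in (10.2, 10.9):
            ov, rov = classify_overlap_interval(R, 10.0, 0.428, None)
            assert ov == rov

    @given(st.floats(-0.5, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_brute_force_interval_check(self, offset):
        S, dur, fce = 5.0, 0.5, 0.44
        R = S + offset
        ov, rov = classify_overlap_interval(R, S, dur, fce)
        assert ov == (S <= R < S + dur)
        assert rov == (S <= R < S + fce)
        assert (not rov) or ov  # restricted implies overlapped


class TestDelayArithmetic:
    def _onsets(self, T, S, R):
        return pd.DataFrame([
            dict(time=T, channel="subject", label="trigger_onset", ref=0),
            dict(time=S, channel="playback", label="stimulus_onset", ref=0),
            dict(time=R, channel="subject", label="response_onset", ref=0),
        ])

    def _plan(self, delay=1.05, motif="silence"):
        return randomize_plan([Condition("highOP", delay, motif)], reps=1,
                              seed=0)

    def test_printed_example(self):
        recs = compute_delays(self._onsets(10.00, 11.05, 11.72), self._plan())
        r = recs[0]
        assert r.stimulus_delay == pytest.approx(1.05)
        assert r.response_delay == pytest.approx(0.67)
        assert r.response_period == pytest.approx(1.72)

    def test_period_identity_holds(self):
        recs = compute_delays(self._onsets(3.1, 4.25, 5.0), self._plan())
        r = recs[0]
        assert r.response_period == pytest.approx(
            r.stimulus_delay + r.response_delay)

    def test_missing_response_flagged(self):
        onsets = self._onsets(10.0, 11.05, 11.72)
        onsets = onsets[onsets.label != "response_onset"]
        r = compute_delays(onsets, self._plan())[0]
        assert r.no_response and np.isnan(r.response_delay)


class TestElaborationScore:
    def test_simple_call_scores_zero(self):
        w = synth_call(CallSpec(n_chucks=0, rate=8000))
        assert elaboration_score(w) == 0.0

    def test_two_chucks_sum_relative_peaks(self):
        w = synth_call(CallSpec(n_chucks=2, chuck_rel_peaks=(0.5, 0.3),
                                rate=8000, whine_duration=0.3))
        assert elaboration_score(w) == pytest.approx(0.8, abs=0.02)

    def test_gain_invariant(self):
        w = synth_call(CallSpec(n_chucks=2, chuck_rel_peaks=(0.5, 0.3),
                                rate=8000, whine_duration=0.3))
        scaled = Waveform(w.samples * 0.21, w.rate, dict(w.meta))
        assert elaboration_score(scaled) == pytest.approx(
            elaboration_score(w), rel=1e-9)

    def test_no_whine_metadata_rejected(self):
        with pytest.raises(ValueError):
            elaboration_score(Waveform(np.ones(100), 8000))


class TestStandardize:
    def test_closed_form(self):
        assert np.allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])

    def test_groupwise_mean_zero_sd_one(self):
        x = [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]
        by = ["a", "a", "a", "b", "b", "b"]
        z = standardize(x, by=by)
        assert np.allclose(z[:3], z[3:])

    def test_joint_standardization_preserves_difference_order(self):
        trig = np.array([0.2, 0.5, 0.9])
        resp = np.array([0.3, 0.4, 1.2])
        z = standardize(np.concatenate([trig, resp]))
        zt, zr = z[:3], z[3:]
        assert np.all(np.sign(zr - zt) == np.sign(resp - trig))


class TestExtraction:
    @pytest.fixture(scope="class")
    def session(self):
        conds = [Condition(s, d, "silence")
                 for s in ("lowOP", "intOP", "highOP")
                 for d in (0.45, 0.9, 1.35)]
        conds += [Condition("highOP", 1.5, "overlap_sync"),
                  Condition("lowOP", 1.05, "tone_short")]
        plan = randomize_plan(conds, reps=2, seed=9, subject_id="M03",
                              warmup_duration=8.0, warmup_interval=2.0)
        log, transport = run_simulated_session(
            plan, seed=7, config=EngineConfig(silent_timeout=30.0))
        return plan, log, transport

    def test_extracted_onsets_match_ground_truth_within_5ms(self, session):
        plan, _, transport = session
        onsets = extract_onsets(transport.recording(), plan)
        subj = onsets[onsets.channel == "subject"]
        gt = transport.ground_truth()
        errs = np.array([np.abs(subj.time - t).min() for t in gt.time])
        assert (errs < 0.005).mean() >= 0.99

    def test_derived_delays_match_commanded_within_5ms(self, session):
        plan, _, transport = session
        from chorusloop import build_stimulus_library

        onsets = extract_onsets(transport.recording(), plan)
        recs = compute_delays(onsets, plan,
                              library=build_stimulus_library(transport.rate))
        ok = [abs(r.stimulus_delay - plan.entries[r.ref].stimulus_delay) < 0.005
              for r in recs if not r.spontaneous]
        assert np.mean(ok) >= 0.99

    def test_empty_subject_channel_still_aligns_playback(self, session):
        plan, _, transport = session
        rec = transport.recording()
        silent = Waveform(np.stack([np.zeros(rec.samples.shape[0]),
                                    rec.samples[:, 1]], axis=1), rec.rate)
        onsets = extract_onsets(silent, plan)
        assert (onsets.channel == "subject").sum() == 0
        assert (onsets.label == "stimulus_onset").sum() == len(plan.entries)

    def test_clock_skew_leaves_delays_unchanged(self, session):
        """Shifting both channels equally cannot change any derived delay."""
        plan, _, transport = session
        from chorusloop import build_stimulus_library

        lib = build_stimulus_library(transport.rate)
        rec = transport.recording()
        shift = int(0.05 * rec.rate)
        shifted = Waveform(np.vstack([np.zeros((shift, 2)), rec.samples]),
                           rec.rate)
        a = records_to_frame(compute_delays(
            extract_onsets(rec, plan), plan, library=lib))
        b = records_to_frame(compute_delays(
            extract_onsets(shifted, plan), plan, library=lib))
        assert np.allclose(a.stimulus_delay, b.stimulus_delay, atol=1e-6)
        assert np.allclose(a.response_delay, b.response_delay,
                           atol=1e-6, equal_nan=True)

    def test_misaligned_count_raises(self, session):
        plan, _, transport = session
        rec = transport.recording()
        # drop the first second of playback (loses warmup interims)
        cut = rec.samples.copy()
        cut[:rec.rate, 1] = 0.0
        with pytest.raises(AlignmentError):
            extract_onsets(Waveform(cut, rec.rate), plan)

    def test_restricted_implies_overlapped_everywhere(self, session):
        plan, _, transport = session
        from chorusloop import build_stimulus_library

        onsets = extract_onsets(transport.recording(), plan)
        recs = compute_delays(onsets, plan,
                              library=build_stimulus_library(transport.rate))
        for r in recs:
            assert (not r.restricted_overlap) or r.overlapped
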