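"""Call and tone synthesis: sweep laws, durations, calibration, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chorusloop import (CallSpec, InvalidSpecError, Waveform, calibrate_peak,
                        interim_call_spec, motif_component_spec, read_wav,
                        stimulus_call_spec, synth_call, synth_tone,
                        synth_whine, write_wav)
from chorusloop.inhibition import f0_trajectory


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestWhine:
    def test_sweep_endpoints_recovered_by_f0_tracker(self):
        spec = CallSpec(whine_duration=0.3, f_start=900, f_end=400,
                        rate=44100, whine_amp_decay=1.0)
        w = synth_whine(spec)
        f0 = f0_trajectory(w)
        v = f0.values[~np.isnan(f0.values)]
        assert abs(v[0] - 900) / 900 < 0.05
        assert abs(v[-1] - 400) / 400 < 0.05

    def test_f0_track_monotone_decreasing(self):
        w = synth_whine(CallSpec(whine_duration=0.35, rate=44100))
        f0 = f0_trajectory(w)
        v = f0.values[~np.isnan(f0.values)]
        # allow tracker jitter of a few Hz but no real reversals
        assert np.all(np.diff(v) < 10.0)

    def test_no_decay_gives_flat_envelope(self):
        spec = CallSpec(whine_duration=0.3, whine_amp_decay=1.0, rate=44100)
        w = synth_whine(spec)
        n = int(0.010 * w.rate)
        assert abs(_rms(w.samples[:n]) - _rms(w.samples[-n:])) \
            / _rms(w.samples[:n]) < 0.05

    def test_envelope_decays_to_commanded_fraction(self):
        spec = CallSpec(whine_duration=0.3, whine_amp_decay=0.25, rate=44100)
        w = synth_whine(spec)
        n = int(0.010 * w.rate)
        ratio = _rms(w.samples[-n:]) / _rms(w.samples[:n])
        assert abs(ratio - 0.25) < 0.05

    @pytest.mark.parametrize("kw", [
        dict(whine_duration=0.0),
        dict(whine_duration=-1.0),
        dict(rate=0),
        dict(f_start=400, f_end=900),      # ascending sweep
        dict(whine_amp_decay=0.0),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(InvalidSpecError):
            synth_whine(CallSpec(**kw))


class TestCall:
    def test_no_chucks_equals_whine(self):
        spec = CallSpec(n_chucks=0, rate=8000)
        assert np.array_equal(synth_call(spec).samples,
                              synth_whine(spec).samples)

    def test_duration_is_closed_form_sum(self):
        spec = CallSpec(whine_duration=0.3, n_chucks=2,
                        chuck_rel_peaks=(0.5, 0.4), chuck_duration=0.04,
                        chuck_gap=0.005, rate=44100)
        w = synth_call(spec)
        assert abs(w.duration - 0.385) <= 1.5 / spec.rate
        # exact in samples: sum of individually rounded components
        expected = (round(0.3 * 44100) + 2 * round(0.04 * 44100)
                    + round(0.005 * 44100))
        assert len(w.samples) == expected

    def test_interim_with_second_chuck_removed_has_one_chuck(self):
        comp = synth_call(motif_component_spec(8000))
        assert len(comp.meta["chucks"]) == 1
        assert len(synth_call(interim_call_spec(8000)).meta["chucks"]) == 2

    def test_chuck_metadata_brackets_bursts(self):
        w = synth_call(stimulus_call_spec("highOP", 8000))
        for on, off in w.meta["chucks"]:
            seg = w.samples[int(on * w.rate):int(off * w.rate)]
            assert np.max(np.abs(seg)) > 0.2 * w.peak

    def test_overloud_chucks_rejected(self):
        with pytest.raises(InvalidSpecError):
            CallSpec(n_chucks=1, chuck_rel_peaks=(1.2,))

    def test_stimulus_library_durations_match_printed_values(self):
        for sid, dur in [("lowOP", 0.428), ("intOP", 0.484),
                         ("highOP", 0.519)]:
            w = synth_call(stimulus_call_spec(sid, 8000))
            assert abs(w.duration - dur) < 1e-9

    def test_full_scale_respected(self):
        for sid in ("lowOP", "intOP", "highOP"):
            w = calibrate_peak(synth_call(stimulus_call_spec(sid, 8000)))
            assert np.max(np.abs(w.samples)) <= 1.0

    def test_seed_reproducibility(self):
        spec = stimulus_call_spec("intOP", 8000)
        assert np.array_equal(synth_call(spec).samples,
                              synth_call(spec).samples)


class TestTone:
    def test_spectral_peak_at_commanded_frequency(self):
        w = synth_tone(1000.0, 0.61, 44100)
        spec = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(len(w.samples), 1 / w.rate)
        assert abs(freqs[np.argmax(spec)] - 1000.0) <= freqs[1] + 1e-9

    @pytest.mark.parametrize("dur", [0.61, 0.31])
    def test_duration(self, dur):
        w = synth_tone(1000.0, dur, 44100)
        assert abs(w.duration - dur) < 1 / w.rate

    def test_ramps_limit_onset_amplitude(self):
        w = synth_tone(1000.0, 0.31, 44100)
        n = int(0.001 * w.rate)
        assert np.max(np.abs(w.samples[:n])) < 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidSpecError):
            synth_tone(1000.0, 0.0, 44100)
        with pytest.raises(InvalidSpecError):
            synth_tone(5000.0, 0.1, 8000)  # at/above Nyquist


class TestCalibration:
    @given(st.floats(0.05, 1.0), st.floats(0.01, 0.99))
    @settings(max_examples=25, deadline=None)
    def test_peak_hits_target_and_preserves_shape(self, target, scale):
        w = Waveform(scale * np.sin(np.linspace(0, 20, 500)), 1000)
        out = calibrate_peak(w, target)
        assert abs(out.peak - target) < 1e-9
        corr = np.corrcoef(w.samples, out.samples)[0, 1]
        assert corr > 0.999999

    def test_idempotent(self):
        w = Waveform(np.sin(np.linspace(0, 20, 500)), 1000)
        once = calibrate_peak(w, 0.5)
        twice = calibrate_peak(once, 0.5)
        assert np.allclose(once.samples, twice.samples, atol=1e-9)

    def test_silent_input_rejected(self):
        with pytest.raises(InvalidSpecError):
            calibrate_peak(Waveform(np.zeros(100), 1000), 0.5)


def test_wav_round_trip(tmp_path):
    w = calibrate_peak(synth_call(stimulus_call_spec("lowOP", 8000)), 0.8)
    path = tmp_path / "call.wav"
    write_wav(path, w)
    back = read_wav(path)
    assert back.rate == w.rate
    assert np.allclose(back.samples, w.samples, atol=1e-6)


def test_callspec_yaml_round_trip(tmp_path):
    spec = stimulus_call_spec("highOP", 44100)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    assert CallSpec.from_file(path) == spec
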