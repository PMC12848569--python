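"""Assembly of pre-stimulus acoustic motifs.

Stimulus calls can be preceded by motifs mimicking the conspecific
stimulation patterns of crowded choruses: two overlapping calls (610 ms),
two synchronous calls (370 ms), a three-call overlapping+synchronous
combination (610 ms), 1000 Hz tones (610 or 310 ms), or silence.  Motifs
are built from the interim call with its second chuck removed, and are
joined onto stimulus calls with a 10 ms equal-power crossfade, so a
610 ms motif leads the stimulus onset by 600 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .callsynth import (CALIBRATION_PEAK, InvalidSpecError, Waveform,
                        calibrate_peak, interim_call_spec, motif_component_spec,
                        stimulus_call_spec, synth_call, synth_tone)

__all__ = ["MOTIF_KINDS", "MOTIF_DURATIONS", "MotifSpec", "build_motif",
           "prepend_motif", "motif_lead", "PresentationRender",
           "StimulusLibrary", "build_stimulus_library"]

#: printed target duration (s) by motif kind
MOTIF_DURATIONS = {
    "silence": 0.0,
    "overlapping": 0.610,
    "synchronous": 0.370,
    "overlap_sync": 0.610,
    "tone_long": 0.610,
    "tone_short": 0.310,
}
MOTIF_KINDS = tuple(MOTIF_DURATIONS)
#: kinds built from conspecific calls (vs tones/silence)
CALL_MOTIFS = ("overlapping", "synchronous", "overlap_sync")

DEFAULT_CROSSFADE = 0.010
TONE_FREQ = 1000.0


@dataclass
class MotifSpec:
    kind: str
    component_call: Optional[Waveform] = None
    target_duration: Optional[float] = None  # defaults to the kind's value
    crossfade: float = DEFAULT_CROSSFADE
    tone_freq: float = TONE_FREQ
    rate: int = 44100
    peak: float = CALIBRATION_PEAK

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise InvalidSpecError(f"unknown motif kind {self.kind!r}")
        if self.target_duration is None:
            self.target_duration = MOTIF_DURATIONS[self.kind]
        if self.kind != "silence":
            if self.crossfade >= self.target_duration:
                raise InvalidSpecError("crossfade must be shorter than the motif")
        if self.kind in CALL_MOTIFS:
            if self.component_call is None:
                raise InvalidSpecError(f"{self.kind} motif needs a component call")
            self.rate = self.component_call.rate
            if self.component_call.duration > self.target_duration + 0.5 / self.rate:
                raise InvalidSpecError(
                    "component call longer than motif target duration")


def _place(buf: np.ndarray, samples: np.ndarray, at: int) -> None:
    buf[at:at + len(samples)] += samples


def build_motif(spec: MotifSpec) -> Waveform:
    """Render a motif to its printed duration (exact in samples).

    Composition rules: ``synchronous`` sums two component copies at zero
    offset; ``overlapping`` offsets the second copy so the total span
    equals the target duration; ``overlap_sync`` is the synchronous pair
    plus one such offset copy.  The offset is solved from the target
    duration (only total span and composition are specified).  Summed
    copies can exceed full scale, so the result is renormalized to the
    calibration peak after assembly.  Component onset times (s) are
    recorded in ``meta['components']``.
    """
    n_target = int(round(spec.target_duration * spec.rate))
    if spec.kind == "silence":
        return Waveform(np.zeros(0), spec.rate,
                        {"motif_kind": "silence", "components": []})
    if spec.kind in ("tone_long", "tone_short"):
        tone = synth_tone(spec.tone_freq, spec.target_duration, spec.rate)
        out = calibrate_peak(tone, spec.peak)
        out.meta = {"motif_kind": spec.kind, "components": [0.0],
                    "tone_freq": spec.tone_freq}
        return out

    comp = spec.component_call.samples
    n_off = n_target - len(comp)
    if n_off < 0:
        raise InvalidSpecError("infeasible offset: component longer than target")
    buf = np.zeros(n_target)
    if spec.kind == "synchronous":
        onsets = [0, 0]
    elif spec.kind == "overlapping":
        onsets = [0, n_off]
    else:  # overlap_sync
        onsets = [0, 0, n_off]
    for at in onsets:
        _place(buf, comp, at)
    out = calibrate_peak(Waveform(buf, spec.rate), spec.peak)
    out.meta = {"motif_kind": spec.kind,
                "components": [a / spec.rate for a in onsets]}
    return out


def motif_lead(motif: Waveform, crossfade: float = DEFAULT_CROSSFADE) -> float:
    """Time by which the motif onset leads the stimulus onset (s)."""
    return 0.0 if len(motif.samples) == 0 else motif.duration - crossfade


def prepend_motif(motif: Waveform, stimulus: Waveform,
                  crossfade: float = DEFAULT_CROSSFADE):
    """Join a motif onto a stimulus call with an equal-power crossfade.

    The last ``crossfade`` seconds of the motif overlap the first
    ``crossfade`` seconds of the stimulus under a cos/sin equal-power
    law, which keeps the junction free of low-amplitude dips.  Returns
    ``(combined, stimulus_onset_time)`` where the onset time is
    ``motif_duration - crossfade``; the stimulus's whine/chuck intervals
    are carried over in ``meta`` shifted by that onset.
    """
    rate = stimulus.rate
    if len(motif.samples) == 0:
        out = stimulus.copy()
        out.meta.setdefault("motif_kind", "silence")
        out.meta["stimulus_onset"] = 0.0
        return out, 0.0
    if motif.rate != rate:
        raise InvalidSpecError("motif and stimulus rates differ")
    n_xf = int(round(crossfade * rate))
    if n_xf > min(len(motif.samples), len(stimulus.samples)):
        raise InvalidSpecError("crossfade longer than motif or stimulus")
    n_m, n_s = len(motif.samples), len(stimulus.samples)
    total = n_m + n_s - n_xf
    buf = np.zeros(total)
    buf[:n_m] = motif.samples
    theta = np.pi / 2 * (np.arange(n_xf) + 0.5) / n_xf
    buf[n_m - n_xf:n_m] *= np.cos(theta)
    buf[n_m - n_xf:] += np.concatenate(
        [stimulus.samples[:n_xf] * np.sin(theta), stimulus.samples[n_xf:]])
    onset = (n_m - n_xf) / rate
    meta = {"motif_kind": motif.meta.get("motif_kind"),
            "components": motif.meta.get("components", []),
            "stimulus_onset": onset}
    for key in ("whine", "chucks"):
        if key in stimulus.meta:
            val = stimulus.meta[key]
            if key == "whine":
                meta[key] = (val[0] + onset, val[1] + onset)
            else:
                meta[key] = [(a + onset, b + onset) for a, b in val]
    return Waveform(buf, rate, meta), onset


@dataclass
class PresentationRender:
    """One motif-prefixed stimulus, rendered and annotated.

    ``lead`` is how long the render's onset precedes the stimulus onset
    (0 for silence motifs); ``first_chuck_end`` is seconds after the
    stimulus onset at which its initial chuck ends (None for stimuli
    with fewer than two chucks).
    """

    stimulus_id: str
    motif_kind: str
    waveform: Waveform
    lead: float
    stimulus_duration: float
    first_chuck_end: Optional[float]


class StimulusLibrary:
    """Calibrated renders of every playback sound used in a session."""

    def __init__(self, rate: int, peak: float = CALIBRATION_PEAK,
                 crossfade: float = DEFAULT_CROSSFADE):
        self.rate = rate
        self.peak = peak
        self.crossfade = crossfade
        self.interim = calibrate_peak(synth_call(interim_call_spec(rate)), peak)
        self.component = calibrate_peak(
            synth_call(motif_component_spec(rate)), peak)
        self._stimuli = {}
        self._cache = {}

    def stimulus(self, stimulus_id: str) -> Waveform:
        if stimulus_id not in self._stimuli:
            w = calibrate_peak(
                synth_call(stimulus_call_spec(stimulus_id, self.rate)), self.peak)
            self._stimuli[stimulus_id] = w
        return self._stimuli[stimulus_id]

    def motif(self, kind: str) -> Waveform:
        key = ("motif", kind)
        if key not in self._cache:
            self._cache[key] = build_motif(MotifSpec(
                kind, component_call=self.component, rate=self.rate,
                peak=self.peak, crossfade=self.crossfade))
        return self._cache[key]

    def presentation(self, stimulus_id: str, motif_kind: str
                     ) -> PresentationRender:
        key = (stimulus_id, motif_kind)
        if key not in self._cache:
            stim = self.stimulus(stimulus_id)
            combined, onset = prepend_motif(self.motif(motif_kind), stim,
                                            self.crossfade)
            chucks = stim.meta.get("chucks", [])
            first_end = chucks[0][1] if len(chucks) >= 2 else None
            self._cache[key] = PresentationRender(
                stimulus_id, motif_kind, combined, onset, stim.duration,
                first_end)
        return self._cache[key]


def build_stimulus_library(rate: int, **kw) -> StimulusLibrary:
    return StimulusLibrary(rate, **kw)
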