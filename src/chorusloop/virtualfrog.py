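"""A simulated gap-detection caller that closes the playback loop.

The virtual frog is a functional caricature of a chorusing male: it
calls endogenously with a median period of ~1.71 s, is refractory for
~0.45 s after each call, and otherwise times its calls by gap detection
— a call is triggered when the drop rate of acoustic inhibition (a
"release") exceeds a threshold scaled down by the caller's current
*permissiveness*.  Permissiveness grows with acoustic stimulation
accumulated since the caller's own last call and with how late in the
call cycle the release occurs, so intense conspecific motifs and late
stimulus delays make small releases (e.g. those inside a rival's whine)
sufficient triggers — the mechanism behind stereotyped call overlap.

All functional forms here (linear stimulation integrals, threshold
division, the logistic latency switch, Gaussian period noise, the
endogenous-breakthrough channel) are this package's own minimal,
monotone inventions; the real species' fitted sensory model is not
reproduced.  Two pathways are deliberately dissociated: *generic*
stimulation (any sound, including tones) feeds the permissiveness that
gates releases and endogenous breakthrough, whereas only *conspecific*
stimulation (voiced energy in the whine band) shortens response
latencies and drives arousal/elaboration.  This reproduces the observed
pattern that tonal motifs raise overlap probabilities like conspecific
motifs do, while leaving response delays and call elaboration
unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .callsynth import (CallSpec, Waveform, calibrate_peak, interim_call_spec,
                        synth_call)
from .inhibition import DEFAULT_HOP, FrameTrack, frames_from_waveform

__all__ = ["FrogParams", "FrogState", "CallEvent", "VirtualFrog",
           "build_call_bank", "simulate_presentations", "simulate_alternation"]


@dataclass
class FrogParams:
    """Virtual-frog parameters.  Times in seconds; stimulation integrals in
    full-scale-RMS-seconds ("stimulation units")."""

    median_period: float = 1.71     # endogenous onset-to-onset call period
    refractory: float = 0.45        # no triggered calls this long after own onset
    min_latency: float = 0.06       # floor on release-to-call latency
    noise_sd: float = 0.12          # s.d. of endogenous period noise
    release_threshold: float = 10.0  # inhibition-units/s at zero permissiveness
    threshold_jitter_sd: float = 0.30   # lognormal sigma, redrawn each cycle
    permissiveness_gain_motif: float = 1.0  # per stimulation unit
    permissiveness_gain_phase: float = 0.15  # per s beyond refractory
    conspecific_weight: float = 0.5  # extra weight of conspecific frames
    latency_scale: float = 0.50     # slow-mode latency above the floor
    latency_threshold: float = 0.17  # conspecific units at the mode switch
    latency_width: float = 0.02     # softness of the switch
    latency_jitter_sd: float = 0.25  # lognormal sigma on the slow component
    breakthrough_base: float = 0.08  # P(endogenous call wins during stimulation)
    breakthrough_gain: float = 0.4  # increase per unit generic permissiveness
    breakthrough_max: float = 0.75
    arousal_gain: float = 3.0       # arousal per conspecific stimulation unit
    arousal_decay: float = 0.15     # 1/s during silence
    arousal_floor: float = 0.02     # below this, endogenous calling stops
    arousal_init: float = 1.0
    arousal_max: float = 2.0
    elaboration_inertia: float = 0.8  # weight of previous call's score
    elaboration_gain: float = 1.0   # arousal -> target elaboration score
    elaboration_max: float = 1.35
    elaboration_init: float = 0.5
    intensity_floor: float = 0.01   # RMS below this counts as silence
    forward_masking_tau: float = 0.05  # s; stimulation envelope decay
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.min_latency < self.refractory < self.median_period):
            raise ValueError("need min_latency < refractory < median_period")

    @classmethod
    def pure_oscillator(cls, **kw) -> "FrogParams":
        """All stimulation pathways off: a free-running noisy oscillator."""
        base = dict(release_threshold=math.inf, breakthrough_base=0.0,
                    breakthrough_gain=0.0, permissiveness_gain_motif=0.0,
                    permissiveness_gain_phase=0.0, arousal_decay=0.0,
                    intensity_floor=math.inf)  # sound never vetoes the timer
        base.update(kw)
        return cls(**base)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "FrogParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class FrogState:
    """Mutable caller state; all levels are >= 0."""

    t: float = 0.0              # current time on the session clock
    t_own: float = 0.0          # onset of the caller's last own call
    last_inh: float = 0.0       # inhibition at the previous frame
    stim_generic: float = 0.0   # generic stimulation integral since own call
    stim_conspecific: float = 0.0  # conspecific stimulation integral
    arousal: float = 1.0
    elaboration: float = 0.5
    eps: float = 1.0            # per-cycle threshold jitter factor
    masking: float = 0.0        # forward-masked stimulation envelope
    pending: Optional[float] = None  # committed upcoming call onset
    next_endog: Optional[float] = None  # scheduled endogenous onset

    @property
    def time_since_own_call(self) -> float:
        return self.t - self.t_own

    @property
    def permissiveness(self) -> float:
        return self.stim_generic + self.stim_conspecific


@dataclass
class CallEvent:
    time: float
    elaboration: float


class VirtualFrog:
    """Frame-driven gap-detection caller.

    Feed it per-frame acoustic features via :meth:`step` (or the
    :meth:`run_frames` / :meth:`run_silence` conveniences) and collect
    the :class:`CallEvent` onsets it emits.
    """

    def __init__(self, params: Optional[FrogParams] = None,
                 rng: Optional[np.random.Generator] = None,
                 hop: float = DEFAULT_HOP):
        self.p = params or FrogParams()
        self.rng = rng if rng is not None else np.random.default_rng(self.p.seed)
        self.hop = hop
        self.state = FrogState()
        self.reset(0.0)

    # -- lifecycle ----------------------------------------------------------

    def _period_draw(self) -> float:
        p = self.p
        draw = p.median_period + p.noise_sd * float(self.rng.standard_normal())
        return max(p.refractory + 0.05, draw)

    def reset(self, t: float = 0.0, own_call_at_start: bool = True) -> None:
        """Start a fresh cycle at time ``t`` (the caller's own call onset)."""
        p = self.p
        s = self.state
        s.t = t
        s.t_own = t if own_call_at_start else t - p.median_period
        s.last_inh = 0.0
        s.stim_generic = 0.0
        s.stim_conspecific = 0.0
        s.arousal = p.arousal_init
        s.elaboration = p.elaboration_init
        s.eps = self._jitter(p.threshold_jitter_sd)
        s.masking = 0.0
        s.pending = None
        s.next_endog = s.t_own + self._period_draw()

    def _jitter(self, sd: float) -> float:
        return float(np.exp(sd * self.rng.standard_normal())) if sd > 0 else 1.0

    def _emit(self, at: float) -> CallEvent:
        p, s = self.p, self.state
        s.t_own = at
        s.stim_generic = 0.0
        s.stim_conspecific = 0.0
        s.eps = self._jitter(p.threshold_jitter_sd)
        s.pending = None
        s.next_endog = at + self._period_draw()
        target = min(p.elaboration_gain * s.arousal, p.elaboration_max)
        s.elaboration = (p.elaboration_inertia * s.elaboration
                         + (1.0 - p.elaboration_inertia) * target)
        return CallEvent(at, s.elaboration)

    # -- core update --------------------------------------------------------

    def step(self, frame: Optional[Sequence[float]], dt: float) -> List[CallEvent]:
        """Advance one frame of ``dt`` seconds.

        ``frame`` is ``(intensity, inhibition, conspecific)`` from the
        trajectory pipeline, or ``None`` for silence.  Returns the calls
        emitted during this frame (at most one).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        p, s = self.p, self.state
        t = s.t
        if frame is None:
            intensity = inh = consp = 0.0
        else:
            intensity, inh, consp = float(frame[0]), float(frame[1]), float(frame[2])
        release = (s.last_inh - inh) / dt
        s.last_inh = inh
        # forward-masked stimulation envelope: brief gaps (inter-note
        # silences) do not count as the stimulation having ended
        s.masking = max(intensity, s.masking * math.exp(-dt / p.forward_masking_tau))
        stimulated = s.masking > p.intensity_floor
        if intensity > p.intensity_floor:
            s.stim_generic += (1.0 + p.conspecific_weight * consp) * intensity * dt
            s.stim_conspecific += consp * intensity * dt
            s.arousal = min(p.arousal_max,
                            s.arousal + p.arousal_gain * consp * intensity * dt)
        elif p.arousal_decay > 0:
            s.arousal *= math.exp(-p.arousal_decay * dt)

        events: List[CallEvent] = []
        if s.pending is not None and t >= s.pending:
            events.append(self._emit(s.pending))
        elif s.pending is None and t - s.t_own >= p.refractory and release > 0:
            phase = t - s.t_own - p.refractory
            perm = (p.permissiveness_gain_motif * s.stim_generic
                    + p.permissiveness_gain_phase * phase)
            theta_eff = p.release_threshold * s.eps / (1.0 + perm)
            if release >= theta_eff:
                slow = p.latency_scale / (1.0 + math.exp(
                    (s.stim_conspecific - p.latency_threshold) / p.latency_width))
                lat = p.min_latency + slow * self._jitter(p.latency_jitter_sd)
                s.pending = t + lat

        if s.pending is None and s.next_endog is not None and t >= s.next_endog:
            if stimulated:
                # the endogenous drive occasionally wins against ongoing
                # inhibition; stimulation accumulated this cycle makes the
                # veto leakier (phase enters through the collision window
                # geometry itself)
                p_bt = min(p.breakthrough_max,
                           p.breakthrough_base + p.breakthrough_gain
                           * p.permissiveness_gain_motif * s.stim_generic)
                if self.rng.random() < p_bt:
                    events.append(self._emit(t))
                else:
                    s.next_endog = t + self._period_draw()
            elif s.arousal >= p.arousal_floor:
                events.append(self._emit(s.next_endog))
            else:
                s.next_endog = None  # too unaroused: fall silent
        s.t = t + dt
        return events

    # -- conveniences -------------------------------------------------------

    def run_frames(self, track: FrameTrack, at: Optional[float] = None
                   ) -> List[CallEvent]:
        """Step through a waveform's frame track starting at time ``at``."""
        s = self.state
        if at is not None:
            if at < s.t:
                raise ValueError("cannot step backwards in time")
            if at > s.t:
                self.run_silence(at)
        events: List[CallEvent] = []
        hop = track.hop
        inten, inh, consp = track.intensity, track.inhibition, track.conspecific
        for i in range(len(track)):
            events += self.step((inten[i], inh[i], consp[i]), hop)
        return events

    def run_silence(self, until: float) -> List[CallEvent]:
        """Advance through silence to time ``until``, event-driven."""
        p, s = self.p, self.state
        events: List[CallEvent] = []
        # resolve the sound-offset transition (possible large release)
        while s.last_inh > 0 and s.t < until:
            events += self.step(None, self.hop)
        while s.t < until:
            # a committed (pending) call silences the endogenous timer;
            # next_endog is redrawn when the pending call is emitted
            t_next = s.pending if s.pending is not None else s.next_endog
            if t_next is None:
                t_next = math.inf
            t_next = max(t_next, s.t)
            if t_next >= until:
                self._decay(until - s.t)
                s.t = until
                break
            self._decay(t_next - s.t)
            s.t = t_next
            if s.pending is not None and s.pending <= t_next:
                events.append(self._emit(s.pending))
            elif s.next_endog is not None and s.next_endog <= t_next:
                if s.masking > p.intensity_floor:
                    # still inside the masked tail of recent stimulation
                    p_bt = min(p.breakthrough_max,
                               p.breakthrough_base + p.breakthrough_gain
                               * p.permissiveness_gain_motif * s.stim_generic)
                    if self.rng.random() < p_bt:
                        events.append(self._emit(s.next_endog))
                    else:
                        s.next_endog = t_next + self._period_draw()
                elif s.arousal >= p.arousal_floor:
                    events.append(self._emit(s.next_endog))
                else:
                    s.next_endog = None
        return events

    def _decay(self, span: float) -> None:
        if span <= 0:
            return
        p, s = self.p, self.state
        if p.arousal_decay > 0:
            s.arousal *= math.exp(-p.arousal_decay * span)
        s.masking *= math.exp(-span / p.forward_masking_tau)

    # -- call production ----------------------------------------------------

    def emit_call(self, call_bank: Sequence[tuple]) -> tuple:
        """Draw the emitted call nearest the caller's elaboration score.

        ``call_bank`` is a sequence of ``(elaboration_score, Waveform)``
        pairs at graded elaboration.  Returns ``(waveform, score)`` where
        ``score`` is the caller's current elaboration state.
        """
        if not call_bank:
            raise ValueError("empty call bank")
        e = self.state.elaboration
        score, wav = min(call_bank, key=lambda sw: abs(sw[0] - e))
        return wav, e


def build_call_bank(rate: int, max_chucks: int = 3) -> List[tuple]:
    """Render subject calls at graded elaboration (0..max_chucks chucks).

    Elaboration score = summed chuck peak amplitudes relative to the
    whine peak, i.e. the sum of the spec's relative chuck peaks.
    """
    peaks = (0.5, 0.45, 0.4)
    bank = []
    for n in range(max_chucks + 1):
        spec = CallSpec(whine_duration=0.33, f_start=910.0, f_end=410.0,
                        n_chucks=n, chuck_rel_peaks=peaks[:n], rate=rate,
                        seed=20 + n)
        w = calibrate_peak(synth_call(spec), 0.8)
        bank.append((float(sum(peaks[:n])), w))
    return bank


# ---------------------------------------------------------------------------
# Event-level experiments
#
# These run the frog against presentation timelines directly (frame
# tracks during sound, event-driven silence in between), without audio
# rendering or an engine in the loop.  Each presentation starts a fresh
# cycle at the trigger-call onset: in the playback protocol every
# stimulus is preceded by a palette-cleansing interim exchange, so
# carry-over of stimulation integrals between presentations is
# deliberately negligible; arousal/elaboration are carried over within
# a simulated trial.
# ---------------------------------------------------------------------------


def _render_track(combined: Waveform) -> FrameTrack:
    return frames_from_waveform(combined)


def simulate_presentations(conditions, reps: int, params: Optional[FrogParams],
                           seed: int, rate: int = 8000,
                           horizon: float = 2.5):
    """Simulate ``reps`` responses to every condition; return a DataFrame.

    Columns: stimulus_id, motif_kind, stimulus_delay, response_delay,
    response_period, overlapped, restricted_overlap, spontaneous,
    elaboration, trigger_elaboration, rep.
    """
    import pandas as pd

    from .motifbuild import build_stimulus_library
    from .respmetrics import classify_overlap_interval

    params = params or FrogParams()
    rng = np.random.default_rng(seed)
    lib = build_stimulus_library(rate)
    tracks = {}
    frog = VirtualFrog(params, rng=rng)
    rows = []
    for rep in range(reps):
        for cond in conditions:
            key = (cond.stimulus_id, cond.motif_kind)
            if key not in tracks:
                entry = lib.presentation(cond.stimulus_id, cond.motif_kind)
                tracks[key] = (entry, _render_track(entry.waveform))
            entry, track = tracks[key]
            delay = cond.stimulus_delay
            arousal, elab = frog.state.arousal, frog.state.elaboration
            frog.reset(0.0)
            frog.state.arousal = arousal  # carried over within the trial
            frog.state.elaboration = elab
            trig_elab = elab
            t_sound = delay - entry.lead
            events = frog.run_silence(t_sound)
            events += frog.run_frames(track, t_sound)
            events += frog.run_silence(delay + entry.stimulus_duration + horizon)
            onsets = [e.time for e in events]
            S = delay
            resp = next((e for e in events if e.time > S), None)
            spont = any(t <= S for t in onsets)
            if resp is None:
                rows.append(dict(stimulus_id=cond.stimulus_id,
                                 motif_kind=cond.motif_kind, stimulus_delay=delay,
                                 response_delay=np.nan, response_period=np.nan,
                                 overlapped=False, restricted_overlap=False,
                                 spontaneous=spont, elaboration=np.nan,
                                 trigger_elaboration=trig_elab, rep=rep))
                continue
            R = resp.time
            ov, rov = classify_overlap_interval(
                R, S, entry.stimulus_duration, entry.first_chuck_end)
            rows.append(dict(stimulus_id=cond.stimulus_id,
                             motif_kind=cond.motif_kind, stimulus_delay=delay,
                             response_delay=R - S, response_period=R,
                             overlapped=ov, restricted_overlap=rov,
                             spontaneous=spont, elaboration=resp.elaboration,
                             trigger_elaboration=trig_elab, rep=rep))
    return pd.DataFrame(rows)


def simulate_alternation(n_cycles: int, params: Optional[FrogParams] = None,
                         seed: int = 0, rate: int = 8000,
                         interim_delay: float = 0.75) -> np.ndarray:
    """Dyadic alternation with interim-call playback; returns call periods.

    Each frog call triggers an interim call ``interim_delay`` later; the
    frog's response to that interim closes the cycle.  Returns the
    onset-to-onset periods (s) of up to ``n_cycles`` cycles.
    """
    params = params or FrogParams()
    rng = np.random.default_rng(seed)
    interim = calibrate_peak(synth_call(interim_call_spec(rate)))
    track = _render_track(interim)
    frog = VirtualFrog(params, rng=rng)
    frog.reset(0.0)
    periods = []
    t_own = 0.0
    for _ in range(n_cycles):
        t_i = t_own + interim_delay
        events = frog.run_silence(t_i)
        events += frog.run_frames(track, t_i)
        deadline = t_i + track.duration + 2 * params.median_period
        while (not any(e.time > t_own for e in events)
               and frog.state.t < deadline):
            events += frog.run_silence(min(deadline, frog.state.t + 0.2))
        nxt = next((e for e in events if e.time > t_own), None)
        if nxt is None:
            break
        periods.append(nxt.time - t_own)
        t_own = nxt.time
    return np.asarray(periods)


# ---------------------------------------------------------------------------
# Simulated transport (audio tier)
# ---------------------------------------------------------------------------


class SimulatedTransport:
    """Deterministic shared-clock transport closing the loop on a frog.

    ``read(n)`` advances the sample clock, stepping the frog over the
    acoustic frames of whatever playback is active (silence otherwise)
    and returning the subject channel (the frog's emitted calls,
    rendered from a graded call bank).  ``schedule`` quantizes to whole
    samples and returns the actual onset time, so scheduling on this
    transport is sample-exact.  The transport retains both channels and
    the ground-truth subject onsets for offline analysis.
    """

    def __init__(self, frog: VirtualFrog, rate: int = 8000,
                 call_bank: Optional[list] = None):
        self.frog = frog
        self.rate = rate
        self.n_hop = int(round(frog.hop * rate))
        if self.n_hop < 1:
            raise ValueError("frame hop below one sample")
        self.n_now = 0
        self._frame_cursor = 0
        self.playbacks: list = []   # (n_start, samples, FrameTrack)
        self.emissions: list = []   # (n_start, samples)
        self.subject_onsets: list = []  # (time, elaboration) ground truth
        self.call_bank = call_bank or build_call_bank(rate)
        self._track_cache: dict = {}

    def now(self) -> float:
        return self.n_now / self.rate

    def schedule(self, waveform: Waveform, at_time: float) -> float:
        n_at = int(round(at_time * self.rate))
        if n_at < self.n_now:
            raise ValueError("cannot schedule output in the past")
        key = id(waveform.samples)
        if key not in self._track_cache:
            self._track_cache[key] = frames_from_waveform(waveform)
        self.playbacks.append((n_at, waveform.samples, self._track_cache[key]))
        self.playbacks.sort(key=lambda p: p[0])
        return n_at / self.rate

    def _frame_input(self, n0: int):
        for n_at, _, track in self.playbacks:
            if n_at > n0:
                break
            j = (n0 - n_at) // self.n_hop
            if j < len(track):
                return (track.intensity[j], track.inhibition[j],
                        track.conspecific[j])
        return None

    def _emit(self, event: CallEvent) -> None:
        wav, _ = self.frog.emit_call(self.call_bank)
        n_at = int(round(event.time * self.rate))
        self.emissions.append((n_at, wav.samples))
        self.subject_onsets.append((n_at / self.rate, event.elaboration))

    def read(self, n_frames: int) -> np.ndarray:
        end = self.n_now + n_frames
        while (self._frame_cursor + 1) * self.n_hop <= end:
            n0 = self._frame_cursor * self.n_hop
            for ev in self.frog.step(self._frame_input(n0),
                                     self.n_hop / self.rate):
                self._emit(ev)
            self._frame_cursor += 1
        out = self._compose(self.emissions, self.n_now, end)
        self.n_now = end
        return out

    @staticmethod
    def _compose(pieces, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start)
        for n_at, samples in pieces:
            a, b = max(n_at, start), min(n_at + len(samples), end)
            if b > a:
                out[a - start:b - start] += samples[a - n_at:b - n_at]
        return out

    def recording(self) -> Waveform:
        """Two-channel session recording (0: subject, 1: playback)."""
        n = self.n_now
        subject = self._compose(self.emissions, 0, n)
        playback = self._compose(
            [(n_at, s) for n_at, s, _ in self.playbacks], 0, n)
        return Waveform(np.stack([subject, playback], axis=1), self.rate)

    def ground_truth(self):
        import pandas as pd

        return pd.DataFrame(self.subject_onsets,
                            columns=["time", "elaboration"])
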