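"""Event-driven closed-loop playback engine.

The engine listens for the subject's call onsets and runs the playback
protocol: a warmup block of interim calls; then, for each plan entry,
the subject's onset (the *trigger*) schedules the motif-prefixed
stimulus so that the stimulus onset lands exactly at trigger +
commanded delay; the subject's response onset schedules a
palette-cleansing interim at a fixed 0.75 s delay; and the response to
that interim becomes the next trigger.

The engine is transport-agnostic: anything with ``read(n)``,
``schedule(waveform, at_time) -> actual_time``, ``now()`` and ``rate``
closes the loop.  The tested implementation is the deterministic
simulated transport in :mod:`chorusloop.virtualfrog`; on it, scheduled
times are exact in samples.  Engine onset timestamps are provisional —
the definitive timing analysis re-derives onsets from the session
recording (:mod:`chorusloop.respmetrics`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Protocol

import numpy as np
import pandas as pd

from .callsynth import Waveform
from .motifbuild import StimulusLibrary, build_stimulus_library
from .scheduler import TrialPlan, plan_to_sequence

__all__ = ["EngineConfig", "Event", "EventLog", "detect_onset",
           "OnsetDetector", "Transport", "run_session",
           "run_simulated_session"]


@dataclass
class EngineConfig:
    """Engine timing parameters (seconds unless noted).

    ``onset_refractory`` must exceed a full call's duration (>= 0.55 s
    here) so that chuck notes and inter-note gaps inside one call cannot
    retrigger the detector.  ``buffer`` is both the read-block size and
    the engine latency budget when scheduling output.
    """

    onset_threshold: float = 0.05   # fraction of full scale, windowed RMS
    onset_window: float = 0.004
    onset_refractory: float = 0.55
    silent_timeout: float = 120.0   # end the session after this much silence
    buffer: float = 0.010
    max_session: float = 3600.0     # hard safety stop


@dataclass
class Event:
    time: float
    label: str
    ref: int


VALID_LABELS = {"trigger_onset", "motif_onset", "stimulus_onset",
                "interim_onset", "response_onset", "session_end",
                "spontaneous", "skipped"}


class EventLog:
    """Timestamped labeled onsets from one session."""

    def __init__(self, events: Optional[List[Event]] = None):
        self.events = list(events or [])

    def add(self, time: float, label: str, ref: int) -> None:
        self.events.append(Event(float(time), label, int(ref)))

    def __len__(self) -> int:
        return len(self.events)

    def times(self, label: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.label == label])

    def by_ref(self, label: str) -> dict:
        return {e.ref: e.time for e in self.events if e.label == label}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([(e.time, e.label, e.ref) for e in self.events],
                          columns=["time", "label", "ref"])
        return df.sort_values("time", kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        df = pd.read_csv(path)
        return cls([Event(r.time, r.label, int(r.ref))
                    for r in df.itertuples()])

    def validate(self, plan: Optional[TrialPlan] = None) -> None:
        """Structural checks: sorted times are non-decreasing, labels are
        known, every stimulus onset has a same-ref trigger before it."""
        df = self.to_frame()
        if not df.time.is_monotonic_increasing:
            raise ValueError("event times not sortable monotonically")
        bad = set(df.label) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown event labels: {bad}")
        trig = self.by_ref("trigger_onset")
        for e in self.events:
            if e.label == "stimulus_onset":
                if e.ref not in trig or trig[e.ref] > e.time:
                    raise ValueError(
                        f"stimulus_onset ref={e.ref} lacks a preceding trigger")
                if plan is not None and not 0 <= e.ref < len(plan.entries):
                    raise ValueError(f"ref {e.ref} outside plan")


class OnsetDetector:
    """Streaming windowed-RMS threshold onset detector.

    An onset is reported when the RMS of a non-overlapping analysis
    window crosses the threshold from below; further crossings within
    the refractory period are suppressed.  Reported time = first sample
    of the crossing window.
    """

    def __init__(self, rate: int, threshold: float = 0.05,
                 window: float = 0.004, refractory: float = 0.55):
        self.rate = rate
        self.threshold = threshold
        self.n_win = max(1, int(round(window * rate)))
        self.refractory = refractory
        self._residual = np.empty(0)
        self._pos = 0  # absolute sample index of the next window start
        self._prev_above = False
        self._last_onset = -np.inf

    def feed(self, samples: np.ndarray) -> List[float]:
        buf = np.concatenate([self._residual, np.asarray(samples, float)])
        n_full = len(buf) // self.n_win
        onsets: List[float] = []
        for k in range(n_full):
            win = buf[k * self.n_win:(k + 1) * self.n_win]
            above = float(np.sqrt(np.mean(win**2))) >= self.threshold
            t = (self._pos + k * self.n_win) / self.rate
            if above and not self._prev_above:
                if t - self._last_onset >= self.refractory:
                    onsets.append(t)
                    self._last_onset = t
            self._prev_above = above
        self._residual = buf[n_full * self.n_win:]
        self._pos += n_full * self.n_win
        return onsets


def detect_onset(frames: np.ndarray, rate: int, threshold: float = 0.05,
                 window: float = 0.004, refractory: float = 0.55
                 ) -> np.ndarray:
    """Offline onset detection on a whole buffer (see OnsetDetector)."""
    det = OnsetDetector(rate, threshold, window, refractory)
    return np.asarray(det.feed(frames))


class Transport(Protocol):
    """Shared-clock audio transport contract."""

    rate: int

    def read(self, n_frames: int) -> np.ndarray: ...

    def schedule(self, waveform: Waveform, at_time: float) -> float: ...

    def now(self) -> float: ...


# session state machine
WARMUP, AWAIT_TRIGGER, AWAIT_RESPONSE, AWAIT_INTERIM_RESPONSE = range(4)


def run_session(plan: TrialPlan, transport: Transport,
                config: Optional[EngineConfig] = None,
                library: Optional[StimulusLibrary] = None) -> EventLog:
    """Run the closed-loop protocol over a transport; return the event log.

    Logged stimulus/interim/motif times are the scheduled output times
    (exact on a deterministic transport); trigger/response times are the
    detector's provisional timestamps.  An entry whose motif lead cannot
    be scheduled ahead of the clock (stimulus delay - lead < latency
    budget) is logged ``skipped``.
    """
    config = config or EngineConfig()
    rate = transport.rate
    lib = library or build_stimulus_library(rate)
    log = EventLog()
    det = OnsetDetector(rate, config.onset_threshold, config.onset_window,
                        config.onset_refractory)
    t0 = transport.now()

    seq = plan_to_sequence(plan)
    n_warm = sum(1 for d in seq if d.ref == -1)
    for k in range(n_warm):
        t = transport.schedule(lib.interim, t0 + k * plan.warmup_interval)
        log.add(t, "interim_onset", -1)
    warmup_end = t0 + plan.warmup_duration

    entries = plan.entries
    idx = 0          # next entry to present
    cur = -1         # entry currently awaiting its response
    state = AWAIT_TRIGGER
    awaiting_after = warmup_end
    last_activity = warmup_end
    n_block = max(1, int(round(config.buffer * rate)))

    def start_presentation(T: float) -> None:
        nonlocal idx, cur, state, awaiting_after
        entry = entries[idx]
        render = lib.presentation(entry.stimulus_id, entry.motif_kind)
        stim_t = T + entry.stimulus_delay
        motif_t = stim_t - render.lead
        if motif_t < transport.now() + config.buffer:
            log.add(T, "skipped", idx)
            idx += 1
            state = AWAIT_TRIGGER
            awaiting_after = T
            return
        log.add(T, "trigger_onset", idx)
        actual = transport.schedule(render.waveform, motif_t)
        if render.lead > 0:
            log.add(actual, "motif_onset", idx)
        log.add(actual + render.lead, "stimulus_onset", idx)
        cur = idx
        idx += 1
        state = AWAIT_RESPONSE
        awaiting_after = actual + render.lead

    while True:
        samples = transport.read(n_block)
        now = transport.now()
        for T in det.feed(samples):
            last_activity = max(last_activity, T)
            if state == AWAIT_TRIGGER:
                if T < awaiting_after or idx >= len(entries):
                    log.add(T, "spontaneous", -1)
                    continue
                start_presentation(T)
            elif state == AWAIT_RESPONSE:
                if T <= awaiting_after:
                    log.add(T, "spontaneous", cur)
                    continue
                log.add(T, "response_onset", cur)
                t_i = transport.schedule(lib.interim, T + plan.interim_delay)
                log.add(t_i, "interim_onset", cur)
                state = AWAIT_INTERIM_RESPONSE
                awaiting_after = t_i
                last_activity = max(last_activity, t_i + lib.interim.duration)
            elif state == AWAIT_INTERIM_RESPONSE:
                if T <= awaiting_after:
                    log.add(T, "spontaneous", cur)
                    continue
                if idx >= len(entries):
                    log.add(T, "session_end", -1)
                    return log
                start_presentation(T)
        if now - last_activity > config.silent_timeout:
            log.add(last_activity + config.silent_timeout, "session_end", -1)
            return log
        if now - t0 > config.max_session:
            log.add(now, "session_end", -1)
            return log


def run_simulated_session(plan: TrialPlan, params=None, rate: int = 8000,
                          seed: int = 0, config: Optional[EngineConfig] = None):
    """Convenience: run a session against a fresh virtual frog.

    Returns ``(log, transport)``; the transport retains the two-channel
    session recording and the ground-truth subject onsets.
    """
    from .virtualfrog import FrogParams, SimulatedTransport, VirtualFrog

    params = params or FrogParams()
    frog = VirtualFrog(params, rng=np.random.default_rng(seed))
    transport = SimulatedTransport(frog, rate=rate)
    log = run_session(plan, transport, config=config)
    return log, transport
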