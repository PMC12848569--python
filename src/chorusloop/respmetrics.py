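"""Offline onset extraction and per-presentation response metrics.

Engine timestamps taken during a live session are only provisional;
the definitive timing analysis re-derives onsets from the two-channel
session recording (channel 0: subject, channel 1: playback) and
computes, for every stimulus presentation:

* stimulus delay  = stimulus onset - trigger onset (S - T)
* response delay  = response onset - stimulus onset (R - S)
* response period = R - T = stimulus delay + response delay
* overlap flags   : ``overlapped`` iff S <= R < S + stimulus duration
  (half-open: an onset exactly at the stimulus offset is alternation);
  ``restricted_overlap`` additionally requires R before the end of the
  stimulus's initial chuck (multi-chuck stimuli only — otherwise it
  equals ``overlapped``)
* call elaboration = summed chuck peak amplitudes relative to the peak
  of the associated whine (0 for a simple call)

All delays use the *stimulus* onset, never the motif onset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .callsynth import Waveform

__all__ = ["ResponseRecord", "extract_onsets", "compute_delays",
           "classify_overlap", "classify_overlap_interval",
           "elaboration_score", "standardize", "records_to_frame",
           "AlignmentError"]


class AlignmentError(RuntimeError):
    """Playback onsets could not be aligned with the session plan."""


@dataclass
class ResponseRecord:
    """Derived metrics for one stimulus presentation."""

    ref: int
    subject_id: str
    stimulus_id: str
    motif_kind: str
    stimulus_delay: float
    response_delay: float
    response_period: float
    overlapped: bool
    restricted_overlap: bool
    elaboration: float = np.nan
    elaboration_z: float = np.nan
    trigger_elaboration: float = np.nan
    onset_time_in_trial: float = np.nan
    no_response: bool = False
    spontaneous: bool = False  # response onset preceded the stimulus onset


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    cols = list(ResponseRecord.__dataclass_fields__)
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


# ---------------------------------------------------------------------------
# Onset extraction
# ---------------------------------------------------------------------------

def _detect_channel(samples: np.ndarray, rate: int, threshold: float,
                    window: float, min_gap: float) -> np.ndarray:
    """Offline onset times (s) by silence-gap segmentation.

    Fine-hop windowed RMS is thresholded into activity regions; regions
    separated by less than ``min_gap`` of silence are merged (chuck gaps
    and motif-internal pauses are far shorter than the silence between
    separate playback events or calls).  Each merged region contributes
    one onset at its first window."""
    n_win = max(1, int(round(window * rate)))
    n_hop = max(1, n_win // 4)
    if len(samples) < n_win:
        return np.array([])
    n_frames = 1 + (len(samples) - n_win) // n_hop
    idx = np.arange(n_win)[None, :] + n_hop * np.arange(n_frames)[:, None]
    rms = np.sqrt(np.mean(samples[idx] ** 2, axis=1))
    above = rms >= threshold
    times = np.flatnonzero(above) * n_hop / rate
    if not len(times):
        return np.array([])
    starts = [times[0]]
    for prev, t in zip(times[:-1], times[1:]):
        if t - prev >= min_gap:
            starts.append(t)
    # refine each region start to the first supra-threshold sample, which
    # removes the window-quantization bias (matters for ramped onsets)
    refined = []
    lo_amp = 0.25 * threshold * np.sqrt(2)
    for t in starts:
        a = max(0, int((t - 2 * window) * rate))
        b = min(len(samples), int((t + 2 * window) * rate))
        hit = np.flatnonzero(np.abs(samples[a:b]) >= lo_amp)
        refined.append((a + hit[0]) / rate if len(hit) else t)
    return np.asarray(refined)


def extract_onsets(recording: Waveform, plan, threshold: float = 0.05,
                   window: float = 0.004, min_gap: float = 0.15):
    """Label onsets in a two-channel session recording.

    Playback-channel onsets are aligned in order with the plan's
    playback directives (raising :class:`AlignmentError` on a count
    mismatch, since order is then ambiguous); subject-channel onsets are
    labeled trigger/response by replaying the session protocol over the
    aligned playback times.  Returns a DataFrame with columns
    ``time, channel, label, ref``.

    Stimulus onsets are reported at the *stimulus* onset (directive
    render onset + motif lead), not the motif onset.
    """
    from .scheduler import plan_to_sequence

    data = recording.samples
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("recording must be two-channel (subject, playback)")
    subject = _detect_channel(data[:, 0], recording.rate, threshold, window,
                              min_gap)
    playback = _detect_channel(data[:, 1], recording.rate, threshold, window,
                               min_gap)
    directives = plan_to_sequence(plan)
    if len(playback) != len(directives):
        raise AlignmentError(
            f"detected {len(playback)} playback onsets but the plan has "
            f"{len(directives)} directives; cannot align by order")
    rows = []
    stim_windows = []  # (stimulus_onset, ref) for labeling subject onsets
    for t, d in zip(playback, directives):
        if d.kind == "stimulus":
            onset = t + d.lead
            rows.append(dict(time=onset, channel="playback",
                             label="stimulus_onset", ref=d.ref))
            if d.lead > 0:
                rows.append(dict(time=t, channel="playback",
                                 label="motif_onset", ref=d.ref))
            stim_windows.append((onset, d.ref))
        else:
            rows.append(dict(time=t, channel="playback",
                             label="interim_onset", ref=d.ref))
    # Subject labeling: each stimulus's trigger is the subject onset nearest
    # the expected trigger time (stimulus onset minus the commanded delay);
    # its response is the first subject onset after the stimulus onset;
    # everything else is spontaneous.
    stim_onsets = np.array([s for s, _ in stim_windows])
    labels = ["spontaneous"] * len(subject)
    refs = [-1] * len(subject)
    for onset, ref in stim_windows:
        expected = onset - plan.entries[ref].stimulus_delay
        if len(subject):
            j = int(np.argmin(np.abs(subject - expected)))
            if labels[j] == "spontaneous" and abs(subject[j] - expected) < 0.1:
                labels[j], refs[j] = "trigger_onset", ref
    for onset, ref in stim_windows:
        after = np.flatnonzero(subject > onset)
        if len(after):
            j = after[0]
            nxt = stim_onsets[stim_onsets > onset]
            if labels[j] == "spontaneous" and (len(nxt) == 0
                                               or subject[j] < nxt[0]):
                labels[j], refs[j] = "response_onset", ref
    for t, lab, ref in zip(subject, labels, refs):
        rows.append(dict(time=float(t), channel="subject", label=lab, ref=ref))
    out = pd.DataFrame(rows, columns=["time", "channel", "label", "ref"])
    return out.sort_values("time", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Per-presentation metrics
# ---------------------------------------------------------------------------

def classify_overlap_interval(R: float, S: float, stimulus_duration: float,
                              first_chuck_end: Optional[float]):
    """Overlap flags from raw times; the single source of truth.

    ``first_chuck_end`` is seconds after the stimulus onset (None for
    stimuli with fewer than two chucks).
    """
    overlapped = bool(S <= R < S + stimulus_duration)
    if first_chuck_end is None:
        restricted = overlapped
    else:
        restricted = bool(S <= R < S + first_chuck_end)
    return overlapped, restricted


def classify_overlap(record: ResponseRecord, stimulus_duration: float,
                     first_chuck_end: Optional[float] = None):
    """Flags for an existing record, from its delays (R - S = response_delay)."""
    return classify_overlap_interval(record.response_delay, 0.0,
                                     stimulus_duration, first_chuck_end)


def compute_delays(onsets: pd.DataFrame, plan, library=None,
                   subject_id: Optional[str] = None) -> List[ResponseRecord]:
    """Build :class:`ResponseRecord` objects from labeled onsets.

    ``library`` (a :class:`~chorusloop.motifbuild.StimulusLibrary`)
    supplies stimulus durations and first-chuck offsets for overlap
    classification; without it the flags are left False and delays are
    still computed.  A presentation whose response is missing is flagged
    ``no_response``; a subject onset between trigger and stimulus marks
    the record ``spontaneous`` (the response delay is still measured
    from the first onset after the stimulus onset).
    """
    subject_id = subject_id or getattr(plan, "subject_id", "subject")
    recs: List[ResponseRecord] = []
    stim = onsets[onsets.label == "stimulus_onset"]
    subj = onsets[onsets.channel == "subject"]
    for _, row in stim.iterrows():
        ref = int(row.ref)
        entry = plan.entries[ref]
        S = float(row.time)
        trig = subj[(subj.label == "trigger_onset") & (subj.ref == ref)]
        resp = subj[(subj.label == "response_onset") & (subj.ref == ref)]
        spont = bool(((subj.time > (S - entry.stimulus_delay))
                      & (subj.time <= S)
                      & (subj.label == "spontaneous")).any())
        if len(trig) == 0:
            continue
        T = float(trig.time.iloc[0])
        if len(resp) == 0:
            recs.append(ResponseRecord(
                ref, subject_id, entry.stimulus_id, entry.motif_kind,
                S - T, np.nan, np.nan, False, False, no_response=True,
                spontaneous=spont, onset_time_in_trial=np.nan))
            continue
        R = float(resp.time.iloc[0])
        dur = fce = None
        if library is not None:
            pr = library.presentation(entry.stimulus_id, entry.motif_kind)
            dur, fce = pr.stimulus_duration, pr.first_chuck_end
        ov, rov = (classify_overlap_interval(R, S, dur, fce)
                   if dur is not None else (False, False))
        recs.append(ResponseRecord(
            ref, subject_id, entry.stimulus_id, entry.motif_kind,
            S - T, R - S, R - T, ov, rov, onset_time_in_trial=R,
            spontaneous=spont or R < S))
    return recs


def elaboration_score(call: Waveform) -> float:
    """Summed chuck peaks relative to the whine peak (0 for simple calls).

    Chuck segments come from synthesis metadata (``meta['whine']`` and
    ``meta['chucks']``); the score is gain-invariant by construction.
    """
    if "whine" not in call.meta:
        raise ValueError("no whine segment in call metadata")
    w0, w1 = call.meta["whine"]
    seg = call.samples[int(w0 * call.rate):int(w1 * call.rate)]
    wpeak = float(np.max(np.abs(seg))) if len(seg) else 0.0
    if wpeak == 0:
        raise ValueError("whine segment is silent")
    total = 0.0
    for c0, c1 in call.meta.get("chucks", []):
        cseg = call.samples[int(c0 * call.rate):int(c1 * call.rate)]
        if len(cseg):
            total += float(np.max(np.abs(cseg)))
    return total / wpeak


def standardize(values, by: Optional[Sequence] = None) -> np.ndarray:
    """Z-score values: (x - mean) / sd, globally or within groups.

    ``by`` gives a group label per value ("within subject"
    standardization); to standardize trigger and response elaborations
    jointly, pass their concatenation and split afterwards.  Raises on
    zero variance.
    """
    x = np.asarray(values, dtype=float)
    if by is None:
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero variance: cannot standardize")
        return (x - np.nanmean(x)) / sd
    out = np.empty_like(x)
    ser = pd.Series(x)
    for _, idx in ser.groupby(list(by)).groups.items():
        g = x[idx]
        sd = np.nanstd(g, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero variance in a group: cannot standardize")
        out[idx] = (g - np.nanmean(g)) / sd
    return out
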