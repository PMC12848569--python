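"""Synthesis of túngara-like calls and tone stimuli.

A túngara frog call begins with a "whine" — a descending frequency sweep
whose amplitude and frequency fall together — optionally followed by one
or more short broadband "chuck" notes.  This module synthesizes such
calls from a :class:`CallSpec`, builds the fixed stimulus/interim call
library used by the playback experiments, and handles peak calibration
and WAV I/O.

All audio is float, full-scale in [-1, 1].  Component durations are
rounded to whole samples individually, so a call's length is the exact
sample-count sum of its parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

__all__ = [
    "InvalidSpecError",
    "Waveform",
    "CallSpec",
    "synth_whine",
    "synth_call",
    "synth_tone",
    "calibrate_peak",
    "stimulus_call_spec",
    "interim_call_spec",
    "motif_component_spec",
    "read_wav",
    "write_wav",
    "DEFAULT_RATE",
]

DEFAULT_RATE = 44100
#: default digital peak level; stand-in for the speaker's SPL calibration
CALIBRATION_PEAK = 0.9
#: broadband chuck noise band (Hz); must sit below Nyquist at any rate used
CHUCK_BAND = (1200.0, 3600.0)


class InvalidSpecError(ValueError):
    """Raised when a synthesis spec violates its invariants."""


def _n(duration: float, rate: float) -> int:
    """Duration in whole samples (round-half-even, like numpy)."""
    return int(round(duration * rate))


@dataclass
class Waveform:
    """Sampled audio: ``samples`` (full-scale in [-1, 1]) at ``rate`` Hz.

    ``meta`` carries synthesis metadata (whine/chuck intervals in seconds,
    relative to the waveform start) used downstream for overlap
    classification and elaboration scoring.
    """

    samples: np.ndarray
    rate: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise InvalidSpecError("rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.rate, dict(self.meta))


@dataclass
class CallSpec:
    """Parameters of a whine + chucks call.

    whine_duration, chuck_duration, chuck_gap in seconds; f_start > f_end
    in Hz (descending sweep); whine_amp_decay is the envelope value at the
    whine end as a fraction of its peak; chuck_rel_peaks are chuck peak
    amplitudes as fractions of the whine peak.
    """

    whine_duration: float = 0.35
    f_start: float = 900.0
    f_end: float = 400.0
    whine_amp_decay: float = 0.25
    n_chucks: int = 0
    chuck_rel_peaks: tuple = ()
    chuck_duration: float = 0.06
    chuck_gap: float = 0.01
    rate: int = DEFAULT_RATE
    sweep_law: str = "exponential"  # or "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        self.chuck_rel_peaks = tuple(float(p) for p in self.chuck_rel_peaks)
        self.validate()

    def validate(self) -> None:
        if self.whine_duration <= 0:
            raise InvalidSpecError("whine_duration must be positive")
        if self.rate <= 0:
            raise InvalidSpecError("rate must be positive")
        if not (0 < self.f_end < self.f_start):
            raise InvalidSpecError("need 0 < f_end < f_start (descending sweep)")
        if self.f_start >= self.rate / 2:
            raise InvalidSpecError("f_start at or above Nyquist")
        if not (0 < self.whine_amp_decay <= 1.0):
            raise InvalidSpecError("whine_amp_decay must be in (0, 1]")
        if self.n_chucks < 0:
            raise InvalidSpecError("n_chucks must be >= 0")
        if len(self.chuck_rel_peaks) != self.n_chucks:
            raise InvalidSpecError("len(chuck_rel_peaks) must equal n_chucks")
        if any(p > 1.0 or p <= 0 for p in self.chuck_rel_peaks):
            raise InvalidSpecError("chuck_rel_peaks must be in (0, 1] (would clip)")
        if self.n_chucks and (self.chuck_duration <= 0 or self.chuck_gap < 0):
            raise InvalidSpecError("chuck_duration must be positive, chuck_gap >= 0")
        if self.sweep_law not in ("exponential", "linear"):
            raise InvalidSpecError(f"unknown sweep_law {self.sweep_law!r}")

    @property
    def total_duration(self) -> float:
        """Closed-form call duration: whine + chucks + inter-chuck gaps."""
        extra = self.n_chucks * self.chuck_duration
        extra += max(0, self.n_chucks - 1) * self.chuck_gap
        return self.whine_duration + extra

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chuck_rel_peaks"] = list(self.chuck_rel_peaks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CallSpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_file(cls, path) -> "CallSpec":
        """Load from YAML or JSON (by extension; YAML parses both)."""
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


def synth_whine(spec: CallSpec) -> Waveform:
    """Synthesize the whine: a descending sweep with a decaying envelope.

    Instantaneous frequency runs from ``f_start`` down to ``f_end``
    (exponentially by default, linearly if ``sweep_law='linear'``); the
    amplitude envelope decays monotonically from 1 to ``whine_amp_decay``
    following the same law, mirroring the concurrent amplitude/frequency
    descent of natural whines.
    """
    spec.validate()
    n = _n(spec.whine_duration, spec.rate)
    t = np.arange(n) / spec.rate
    T = spec.whine_duration
    if spec.sweep_law == "exponential":
        k = spec.f_end / spec.f_start
        # phase(t) = 2*pi * f_start * T/ln(k) * (k**(t/T) - 1)
        phase = 2 * np.pi * spec.f_start * T / np.log(k) * (k ** (t / T) - 1.0)
        env = spec.whine_amp_decay ** (t / T)
    else:
        f = spec.f_start + (spec.f_end - spec.f_start) * t / T
        phase = 2 * np.pi * np.cumsum(f) / spec.rate
        env = 1.0 + (spec.whine_amp_decay - 1.0) * t / T
    samples = env * np.sin(phase)
    return Waveform(samples, spec.rate, {"whine": (0.0, n / spec.rate), "chucks": []})


def _synth_chuck(spec: CallSpec, rel_peak: float, rng: np.random.Generator) -> np.ndarray:
    """One broadband chuck: band-limited noise, fast attack, decaying tail."""
    n = _n(spec.chuck_duration, spec.rate)
    noise = rng.standard_normal(n)
    lo, hi = CHUCK_BAND
    hi = min(hi, 0.45 * spec.rate)  # keep band under Nyquist at low rates
    sos = _chuck_sos(spec.rate, lo, hi)
    from scipy.signal import sosfiltfilt

    burst = sosfiltfilt(sos, noise)
    t = np.arange(n) / spec.rate
    attack = np.minimum(1.0, t / 0.002)
    decay = 0.3 ** (t / spec.chuck_duration)  # tail falls to 30% of peak
    burst *= attack * decay
    peak = np.max(np.abs(burst))
    if peak > 0:
        burst *= rel_peak / peak
    return burst


def _chuck_sos(rate: float, lo: float, hi: float):
    from scipy.signal import butter

    return butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")


def synth_call(spec: CallSpec) -> Waveform:
    """Synthesize a full call: whine followed by ``n_chucks`` chucks.

    Chuck onset/offset times (seconds from call start) are recorded in
    ``meta['chucks']``; total length is the sample-exact sum of the
    whine, chuck and gap sample counts.
    """
    whine = synth_whine(spec)
    if spec.n_chucks == 0:
        return whine
    rng = np.random.default_rng(spec.seed)
    parts = [whine.samples]
    chucks = []
    pos = len(whine.samples)
    n_gap = _n(spec.chuck_gap, spec.rate)
    for i, rel in enumerate(spec.chuck_rel_peaks):
        if i > 0:
            parts.append(np.zeros(n_gap))
            pos += n_gap
        burst = _synth_chuck(spec, rel, rng)
        chucks.append((pos / spec.rate, (pos + len(burst)) / spec.rate))
        parts.append(burst)
        pos += len(burst)
    samples = np.concatenate(parts)
    meta = {"whine": (0.0, len(whine.samples) / spec.rate), "chucks": chucks,
            "chuck_rel_peaks": list(spec.chuck_rel_peaks)}
    return Waveform(samples, spec.rate, meta)


def synth_tone(freq: float, duration: float, rate: int = DEFAULT_RATE,
               ramp: float = 0.005) -> Waveform:
    """Constant-frequency sinusoid with short cosine on/off ramps.

    Ramps (default 5 ms, never more) avoid onset/offset clicks.
    """
    if duration <= 0:
        raise InvalidSpecError("duration must be positive")
    if rate <= 0:
        raise InvalidSpecError("rate must be positive")
    if freq >= rate / 2:
        raise InvalidSpecError("freq must be below Nyquist")
    ramp = min(ramp, 0.005, duration / 2)
    n = _n(duration, rate)
    t = np.arange(n) / rate
    samples = np.sin(2 * np.pi * freq * t)
    n_r = _n(ramp, rate)
    if n_r > 0:
        win = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_r) / n_r)
        samples[:n_r] *= win
        samples[-n_r:] *= win[::-1]
    return Waveform(samples, rate, {"tone_freq": freq})


def calibrate_peak(w: Waveform, target_peak: float = CALIBRATION_PEAK) -> Waveform:
    """Scale a waveform so its absolute peak equals ``target_peak``.

    Digital stand-in for speaker SPL calibration: a single scalar gain,
    shape-preserving.  Raises on silent input.
    """
    if not (0 < target_peak <= 1.0):
        raise InvalidSpecError("target_peak must be in (0, 1]")
    peak = w.peak
    if peak == 0.0:
        raise InvalidSpecError("cannot calibrate a silent waveform")
    return Waveform(w.samples * (target_peak / peak), w.rate, dict(w.meta))


# ---------------------------------------------------------------------------
# Stimulus library
#
# Synthetic stand-ins for the experiment's field-recorded calls.  Total
# durations follow the printed values (low OP 0.428 s < intermediate OP
# 0.484 s < high OP 0.519 s); the extra duration of the multi-chuck calls
# comes from additional chuck notes, as in the originals.  The interim
# call carries two chucks; the motif component is the interim with its
# second chuck removed (0.370 s, the synchronous-motif span).
# ---------------------------------------------------------------------------

_CHUCK = dict(chuck_duration=0.06, chuck_gap=0.01)

_STIMULUS_SPECS = {
    # id: (whine_duration, chuck_rel_peaks, f_start, f_end, seed)
    "lowOP": (0.368, (0.45,), 900.0, 400.0, 11),
    "intOP": (0.354, (0.50, 0.45), 880.0, 410.0, 12),
    "highOP": (0.389, (0.55, 0.50), 920.0, 390.0, 13),
}


def stimulus_call_spec(call_id: str, rate: int = DEFAULT_RATE) -> CallSpec:
    """Spec for one of the three stimulus calls (lowOP / intOP / highOP)."""
    try:
        wd, peaks, f0, f1, seed = _STIMULUS_SPECS[call_id]
    except KeyError:
        raise InvalidSpecError(f"unknown stimulus id {call_id!r}") from None
    return CallSpec(whine_duration=wd, f_start=f0, f_end=f1, n_chucks=len(peaks),
                    chuck_rel_peaks=peaks, rate=rate, seed=seed, **_CHUCK)


def interim_call_spec(rate: int = DEFAULT_RATE) -> CallSpec:
    """The fixed "palette-cleansing" interim call (whine + two chucks)."""
    return CallSpec(whine_duration=0.31, f_start=890.0, f_end=405.0, n_chucks=2,
                    chuck_rel_peaks=(0.5, 0.45), rate=rate, seed=14, **_CHUCK)


def motif_component_spec(rate: int = DEFAULT_RATE) -> CallSpec:
    """Interim call with its second chuck removed: the motif building block."""
    base = interim_call_spec(rate)
    return replace(base, n_chucks=1, chuck_rel_peaks=base.chuck_rel_peaks[:1])


# ---------------------------------------------------------------------------
# WAV I/O (float32 PCM)
# ---------------------------------------------------------------------------

def write_wav(path, w: Waveform) -> None:
    wavfile.write(str(path), int(w.rate), w.samples.astype(np.float32))


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return Waveform(data, int(rate))
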