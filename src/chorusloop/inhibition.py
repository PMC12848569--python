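"""Amplitude, fundamental-frequency and inhibition trajectories.

The gap-detection account of túngara call timing holds that a male's
readiness to call is suppressed by acoustic "inhibition" that tracks both
the amplitude and the spectral content of what he hears, and that calls
are triggered by abrupt *releases* (drops) in that inhibition.  This
module computes windowed trajectories of RMS amplitude and fundamental
frequency, projects them through a frequency-sensitivity function into a
relative inhibition trajectory, and differentiates that into a release
rate.

The frequency-sensitivity function ``S`` is the single pluggable
stand-in in this package: the fitted sensory model of the species is not
reproduced here, and the default is a documented log-Gaussian band-pass
centred near the whine's starting frequency (so inhibition falls faster
than amplitude as the whine sweeps down, producing the moderate release
shortly after whine onsets that the gap-detection account requires).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .callsynth import Waveform

__all__ = [
    "Trajectory",
    "FrameTrack",
    "amplitude_trajectory",
    "f0_trajectory",
    "inhibition_trajectory",
    "release_rate",
    "log_gaussian_sensitivity",
    "frames_from_waveform",
    "DEFAULT_WINDOW",
    "DEFAULT_HOP",
    "SPECIES_BAND",
]

DEFAULT_WINDOW = 0.010  # s; resolves 60 ms latencies with >= 10 frames
DEFAULT_HOP = 0.005  # s
#: f0 range treated as conspecific (whine sweep band), Hz
SPECIES_BAND = (300.0, 950.0)
#: default sensitivity-curve centre/width (Hz, octaves)
SENSITIVITY_CENTER = 850.0
SENSITIVITY_WIDTH_OCT = 0.40


@dataclass
class Trajectory:
    """A uniformly hopped time series of per-window values.

    ``values`` may contain NaN where the quantity is undefined (for f0:
    unvoiced or low-energy windows).
    """

    times: np.ndarray
    values: np.ndarray
    window: float
    hop: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


def _frame(samples: np.ndarray, n_win: int, n_hop: int) -> np.ndarray:
    """View of overlapping windows, one per row (trailing partial dropped)."""
    n_frames = 1 + (len(samples) - n_win) // n_hop
    if n_frames < 1:
        raise ValueError("window longer than signal")
    idx = np.arange(n_win)[None, :] + n_hop * np.arange(n_frames)[:, None]
    return samples[idx]


def _windowed_rms(w: Waveform, window: float, hop: float) -> Trajectory:
    """Absolute windowed RMS (fraction of full scale), times at window starts."""
    if not (0 < hop <= window):
        raise ValueError("need window >= hop > 0")
    n_win, n_hop = int(round(window * w.rate)), int(round(hop * w.rate))
    frames = _frame(w.samples, n_win, n_hop)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    times = np.arange(len(rms)) * n_hop / w.rate
    return Trajectory(times, rms, window, hop)


def amplitude_trajectory(w: Waveform, window: float = DEFAULT_WINDOW,
                         hop: float = DEFAULT_HOP) -> Trajectory:
    """Relative RMS amplitude trajectory, normalized so its maximum is 1.

    A silent input yields an all-zero trajectory (flagged by the zeros
    themselves rather than an error, so silent stretches of recordings
    can be processed uniformly).
    """
    tr = _windowed_rms(w, window, hop)
    peak = tr.values.max()
    if peak > 0:
        tr.values = tr.values / peak
    return tr


def f0_trajectory(w: Waveform, window: float = DEFAULT_WINDOW,
                  hop: float = DEFAULT_HOP, fmin: float = 250.0,
                  fmax: float = 1200.0, voiced_threshold: float = 0.5,
                  energy_threshold: float = 0.05) -> Trajectory:
    """Per-window fundamental-frequency estimate via autocorrelation.

    Windows whose normalized autocorrelation peak falls below
    ``voiced_threshold``, or whose RMS is below ``energy_threshold``
    times the trajectory's maximum RMS, are marked missing (NaN) —
    broadband chucks and silence come out unvoiced.  Peak lags are
    refined by parabolic interpolation.
    """
    if not (0 < fmin < fmax < w.rate / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    n_win, n_hop = int(round(window * w.rate)), int(round(hop * w.rate))
    frames = _frame(w.samples, n_win, n_hop)
    frames = frames - frames.mean(axis=1, keepdims=True)
    # autocorrelation of every window at once, via rfft
    nfft = int(2 ** np.ceil(np.log2(2 * n_win)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :n_win]
    # unbias: the raw estimate tapers with lag, dragging peaks short
    # (sharpest for low f0 in short windows)
    ac = ac / np.maximum(n_win - np.arange(n_win), 1)[None, :]
    ac0 = ac[:, 0].copy()
    ac0[ac0 == 0] = 1.0
    lag_lo = max(2, int(np.floor(w.rate / fmax)))
    lag_hi = min(n_win - 2, int(np.ceil(w.rate / fmin)))
    if lag_hi <= lag_lo:
        raise ValueError("window too short for fmin at this rate")
    search = ac[:, lag_lo:lag_hi + 1]
    # candidate lags are local maxima of the autocorrelation; among those
    # within 25% of the global peak, take the shortest lag.  This avoids
    # subharmonic (octave-down) locking and follows the higher-pitched
    # source when two sweeps overlap.
    m = search.max(axis=1, keepdims=True)
    inner = search[:, 1:-1]
    is_peak = ((inner >= search[:, :-2]) & (inner >= search[:, 2:])
               & (inner >= 0.75 * m))
    has_peak = is_peak.any(axis=1)
    k = np.where(has_peak, np.argmax(is_peak, axis=1) + 1,
                 search.argmax(axis=1)) + lag_lo
    # parabolic refinement around the integer peak lag
    y0, y1, y2 = (ac[np.arange(len(k)), k - 1], ac[np.arange(len(k)), k],
                  ac[np.arange(len(k)), k + 1])
    denom = y0 - 2 * y1 + y2
    with np.errstate(invalid="ignore", divide="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    f0 = w.rate / (k + shift)
    strength = ac[np.arange(len(k)), k] / ac0
    rms = np.sqrt(np.mean((frames + 0) ** 2, axis=1))
    peak_rms = rms.max() if rms.max() > 0 else 1.0
    voiced = (strength >= voiced_threshold) & (rms >= energy_threshold * peak_rms)
    f0 = np.where(voiced, f0, np.nan)
    times = np.arange(len(f0)) * n_hop / w.rate
    return Trajectory(times, f0, window, hop)


def log_gaussian_sensitivity(center: float = SENSITIVITY_CENTER,
                             width_oct: float = SENSITIVITY_WIDTH_OCT,
                             ) -> Callable[[np.ndarray], np.ndarray]:
    """Log-Gaussian band-pass sensitivity: S(f) = exp(-log2(f/center)^2 / 2w^2)."""

    def S(f):
        f = np.asarray(f, dtype=float)
        return np.exp(-(np.log2(f / center)) ** 2 / (2 * width_oct**2))

    return S


def inhibition_trajectory(amp: Trajectory, f0: Trajectory,
                          weighting: Optional[Callable] = None,
                          broadband_default: float = SENSITIVITY_CENTER,
                          rescale: bool = True) -> Trajectory:
    """Project amplitude and f0 trajectories into relative inhibition.

    inhibition(t) = amp(t) * S(f0(t)), with missing f0 evaluated at
    ``broadband_default`` (so broadband chucks inhibit at full band-pass
    weight).  Rescaled to max 1 by default ("relative inhibition");
    pass ``rescale=False`` to keep the amplitude scale.
    """
    if len(amp.times) != len(f0.times) or amp.hop != f0.hop:
        raise ValueError("amplitude and f0 trajectories must share a time base")
    S = weighting or log_gaussian_sensitivity()
    f = np.where(np.isnan(f0.values), broadband_default, f0.values)
    inh = amp.values * S(f)
    inh = np.where(amp.values <= 0, 0.0, inh)
    if rescale:
        peak = inh.max()
        if peak > 0:
            inh = inh / peak
    return Trajectory(amp.times.copy(), inh, amp.window, amp.hop)


def release_rate(inh: Trajectory) -> Trajectory:
    """Negative slope of inhibition, clipped at zero: only releases count.

    Frame k carries the drop from frame k-1 to k divided by the hop
    (units: inhibition per second); frame 0 is zero.
    """
    if len(inh.values) < 2:
        raise ValueError("need at least 2 frames")
    drop = np.concatenate([[0.0], inh.values[:-1] - inh.values[1:]]) / inh.hop
    return Trajectory(inh.times.copy(), np.clip(drop, 0.0, None), inh.window, inh.hop)


@dataclass
class FrameTrack:
    """Per-frame acoustic features of one waveform, as heard by a caller.

    ``intensity``: absolute windowed RMS (fraction of full scale);
    ``inhibition``: intensity weighted by the frequency-sensitivity curve
    (absolute, not rescaled, so magnitudes compare across waveforms);
    ``conspecific``: 1.0 where a voiced f0 falls inside the species'
    whine band, else 0.0.  ``hop`` in seconds.
    """

    intensity: np.ndarray
    inhibition: np.ndarray
    conspecific: np.ndarray
    hop: float

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def duration(self) -> float:
        return len(self.intensity) * self.hop


def frames_from_waveform(w: Waveform, window: float = DEFAULT_WINDOW,
                         hop: float = DEFAULT_HOP,
                         weighting: Optional[Callable] = None,
                         species_band: tuple = SPECIES_BAND,
                         smooth: int = 3) -> FrameTrack:
    """Run the full per-frame pipeline on a waveform for a virtual listener.

    The inhibition track is median-filtered over ``smooth`` frames: a
    sensory smoothing step that suppresses single-frame glitches (noise
    fluctuations inside chucks, f0 misestimates where calls overlap)
    while leaving genuine multi-frame releases — note offsets — intact.
    """
    rms = _windowed_rms(w, window, hop)
    f0 = f0_trajectory(w, window, hop)
    S = weighting or log_gaussian_sensitivity()
    f = np.where(np.isnan(f0.values), SENSITIVITY_CENTER, f0.values)
    if smooth and smooth > 1 and len(f) >= smooth + 2:
        from scipy.ndimage import median_filter

        # suppress isolated source-flips of the f0 tracker where calls
        # overlap; genuine sweeps/transitions move by at most one frame
        f = median_filter(f, size=smooth + 2, mode="nearest")
    inh = np.where(rms.values > 0, rms.values * S(f), 0.0)
    if smooth and smooth > 1 and len(inh) >= smooth:
        from scipy.ndimage import median_filter

        inh = median_filter(inh, size=smooth, mode="nearest")
    lo, hi = species_band
    consp = ((~np.isnan(f0.values)) & (f0.values >= lo) & (f0.values <= hi))
    return FrameTrack(rms.values, inh, consp.astype(float), hop)
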