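"""Frequency-modulated fiber-photometry analysis and event alignment.

Two excitation LEDs are sinusoidally modulated at distinct carrier
frequencies (signal 470 nm at 200 Hz, reference 565 nm at 250 Hz) and the
summed fluorescence is digitized at 4 kHz.  Per channel, demodulation takes
the short-time spectral power of the band nearest the carrier (spectrogram
with a 216-sample window and 108-sample overlap, i.e. a 108-sample hop:
one output sample every 27 ms at 4 kHz).  Slow photobleaching is removed
with a 30 s rolling z-score, applied to the raw trace before demodulation
and again to the demodulated trace when z-scored output is requested.

Behavioral video frames are synchronized through TTL pulses recorded at the
start and end of the session on a companion channel: frame times are
linearly interpolated between the two pulses and each frame is mapped to
the nearest demodulated sample.  Signals are aligned to behavioral events
(approach start, retreat start, retreat end), and the retreat-associated
response is the baseline-subtracted mean over 1 s before to 1 s after
retreat start.  Group summaries average within animal across bouts, then
across animals.

Fluorescence-lifetime traces (ns) follow the same event-alignment path
after moving-average downsampling to 10 Hz (20 Hz for fast assays).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal as spsig

__all__ = [
    "RawPhotometry",
    "DemodulatedSignal",
    "LifetimeSignal",
    "EventAlignedMatrix",
    "GroupAverage",
    "rolling_zscore",
    "demodulate_fm",
    "detect_sync_pulses",
    "build_sync_map",
    "align_to_events",
    "window_response",
    "strata_means",
    "downsample_moving_average",
    "group_average",
]

DEFAULT_CARRIERS = {"signal": 200.0, "reference": 250.0}


@dataclass
class RawPhotometry:
    """4 kHz FM trace plus sync channel; ``carriers`` maps channel name to
    its modulation frequency in Hz."""

    signal: np.ndarray
    sync: np.ndarray
    fs: float = 4000.0
    carriers: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CARRIERS))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.sync = np.asarray(self.sync, dtype=float)
        if max(self.carriers.values()) * 2 >= self.fs:
            raise ValueError("carrier at or above Nyquist")


@dataclass
class DemodulatedSignal:
    """Per-carrier demodulated power on a common time lattice."""

    channels: Dict[str, np.ndarray]
    times: np.ndarray            # s, window-center convention
    dt: float                    # output sampling period, s
    zscored: bool = False

    def __len__(self) -> int:
        return self.times.size


@dataclass
class LifetimeSignal:
    """Fluorescence lifetime (ns) time series."""

    values: np.ndarray
    rate: float                  # Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass
class EventAlignedMatrix:
    """Trials x relative-time matrix of signal snippets."""

    data: np.ndarray             # (n_trials, n_lags)
    lags: np.ndarray             # s, relative to the alignment event
    event: str = "retreat_start"
    n_dropped: int = 0           # events whose window fell off the signal

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class GroupAverage:
    mean: np.ndarray
    sem: np.ndarray
    n_animals: int
    sem_defined: bool


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def rolling_zscore(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling z-score: (x - rolling mean) / rolling std over a
    ``window``-sample centered window, shrunk to the valid range at the
    edges.  Samples with zero rolling std map to 0.

    The 30 s detrending window of the standard pipeline is 12000 samples at
    4 kHz raw rate.
    """
    x = np.asarray(x, dtype=float)
    if window > x.size:
        raise ValueError("window longer than the series")
    r = pd.Series(x).rolling(window, center=True, min_periods=1)
    mu = r.mean().to_numpy()
    sd = r.std(ddof=1).to_numpy()
    out = np.zeros_like(x)
    ok = np.nan_to_num(sd) > 0
    out[ok] = (x[ok] - mu[ok]) / sd[ok]
    return out


# ---------------------------------------------------------------------------
# demodulation
# ---------------------------------------------------------------------------

def demodulate_fm(raw: RawPhotometry, window: int = 216, hop: int = 108,
                  taper: Union[str, tuple] = ("tukey", 0.25),
                  zscore: bool = False, zscore_window_s: float = 30.0,
                  detrend: bool = False) -> DemodulatedSignal:
    """Demodulate each carrier as short-time spectral power.

    A spectrogram with ``window`` samples per segment and overlap
    ``window - hop`` is computed; per carrier, the frequency band nearest
    the carrier frequency is extracted as the demodulated signal.  At the
    defaults (216/108 at 4 kHz) the output sampling period is 27 ms and the
    output length is floor((N - window)/hop) + 1.

    ``detrend`` applies the 30 s rolling z-score to the raw trace first;
    ``zscore`` passes the demodulated power through an additional rolling
    z-score of ``zscore_window_s`` (expressed in output samples).
    """
    if hop > window:
        raise ValueError("hop must not exceed window")
    x = raw.signal
    if window > x.size:
        raise ValueError("window longer than the recording")
    for name, fc in raw.carriers.items():
        if fc * 2 >= raw.fs:
            raise ValueError(f"carrier {name!r} at {fc} Hz above Nyquist")
    if detrend:
        x = rolling_zscore(x, int(round(30.0 * raw.fs)))
    freqs, times, sxx = spsig.spectrogram(
        x, fs=raw.fs, window=spsig.get_window(taper, window),
        nperseg=window, noverlap=window - hop, detrend=False, mode="psd")
    dt = hop / raw.fs
    channels = {}
    for name, fc in raw.carriers.items():
        band = int(np.argmin(np.abs(freqs - fc)))
        y = sxx[band].astype(float)
        if zscore:
            # shrink the z window on recordings shorter than it
            zwin = min(max(2, int(round(zscore_window_s / dt))), y.size)
            y = rolling_zscore(y, zwin)
        channels[name] = y
    return DemodulatedSignal(channels=channels, times=times, dt=dt,
                             zscored=zscore)


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def detect_sync_pulses(sync: np.ndarray, fs: float) -> np.ndarray:
    """Rising-edge times of TTL pulses, thresholded at half the peak."""
    sync = np.asarray(sync, dtype=float)
    peak = sync.max()
    if peak <= 0:
        return np.array([])
    above = sync >= 0.5 * peak
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    return edges / fs


def build_sync_map(sync: np.ndarray, fs: float, n_frames: int,
                   demod_times: np.ndarray) -> np.ndarray:
    """Map each video frame to the nearest demodulated sample.

    Exactly one start and one end pulse are required; frame times are
    linearly interpolated between the two pulse times.
    """
    pulses = detect_sync_pulses(sync, fs)
    if pulses.size != 2:
        raise ValueError(
            f"expected exactly 2 sync pulses (start, end); found {pulses.size}")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    frame_times = np.linspace(pulses[0], pulses[1], n_frames)
    demod_times = np.asarray(demod_times, dtype=float)
    idx = np.searchsorted(demod_times, frame_times)
    idx = np.clip(idx, 1, demod_times.size - 1)
    left_closer = (frame_times - demod_times[idx - 1]
                   <= demod_times[idx] - frame_times)
    return np.where(left_closer, idx - 1, idx)


# ---------------------------------------------------------------------------
# event alignment and quantification
# ---------------------------------------------------------------------------

def align_to_events(values: np.ndarray, dt: float,
                    event_samples: Sequence[int], window: float = 1.0,
                    event: str = "retreat_start") -> EventAlignedMatrix:
    """Snippets of ``values`` around each event sample on a common relative
    time lattice [-window, +window].  Events whose window is truncated by
    the ends of the recording are dropped and counted."""
    values = np.asarray(values, dtype=float)
    w = int(round(window / dt))
    if w < 1:
        raise ValueError("window shorter than one sample")
    rows = []
    dropped = 0
    for s in event_samples:
        s = int(s)
        if s - w < 0 or s + w >= values.size:
            dropped += 1
            continue
        rows.append(values[s - w:s + w + 1])
    if not rows:
        raise ValueError("no events with a complete window")
    return EventAlignedMatrix(data=np.vstack(rows),
                              lags=np.arange(-w, w + 1) * dt,
                              event=event, n_dropped=dropped)


def window_response(aligned: EventAlignedMatrix, t_from: float = -1.0,
                    t_to: float = 1.0,
                    baseline: Optional[Tuple[float, float]] = (-3.0, -1.0),
                    mode: str = "mean") -> np.ndarray:
    """Per-trial response: mean (or peak) of the baseline-subtracted signal
    over [t_from, t_to] around the event.

    ``baseline`` is a (from, to) window on the same lattice whose per-trial
    mean is subtracted first (None disables subtraction); the default
    [-3, -1] s pre-event window requires the alignment window to cover it.
    """
    lags = aligned.lags
    sel = (lags >= t_from - 1e-12) & (lags <= t_to + 1e-12)
    if not sel.any():
        raise ValueError("empty response window")
    data = aligned.data
    if baseline is not None:
        bsel = (lags >= baseline[0] - 1e-12) & (lags <= baseline[1] + 1e-12)
        if not bsel.any():
            raise ValueError("baseline window outside the aligned lattice")
        data = data - data[:, bsel].mean(axis=1, keepdims=True)
    if mode == "mean":
        return data[:, sel].mean(axis=1)
    if mode == "peak":
        return data[:, sel].max(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def strata_means(per_trial: Sequence[float], stratum: int = 10
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Means of consecutive non-overlapping groups of ``stratum`` trials;
    a final partial stratum is retained.  Returns (means, sizes)."""
    x = np.asarray(per_trial, dtype=float)
    if x.size == 0:
        raise ValueError("no trials")
    if stratum < 1:
        raise ValueError("stratum must be >= 1")
    bounds = np.arange(0, x.size, stratum)
    means = np.array([x[b:b + stratum].mean() for b in bounds])
    sizes = np.array([min(stratum, x.size - b) for b in bounds])
    return means, sizes


def downsample_moving_average(x: LifetimeSignal, target_rate: float) -> LifetimeSignal:
    """Non-overlapping block means down to ``target_rate`` Hz.

    A non-integer decimation ratio is floored to the nearest integer block
    size with a warning; the returned signal carries the realized rate.
    """
    if target_rate > x.rate:
        raise ValueError("target rate above native rate")
    if target_rate == x.rate:
        return LifetimeSignal(x.values.copy(), x.rate)
    ratio = x.rate / target_rate
    block = int(ratio)
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"non-integer decimation ratio {ratio:.3f}; using block size {block}")
    else:
        block = int(round(ratio))
    n = (x.values.size // block) * block
    values = x.values[:n].reshape(-1, block).mean(axis=1)
    return LifetimeSignal(values, x.rate / block)


def group_average(per_animal: Sequence[np.ndarray]) -> GroupAverage:
    """Two-stage group trace: average within each animal across trials,
    then across animals; SEM across animals (0, flagged, for one animal).
    Animals with unequal trial counts get equal weight."""
    if len(per_animal) == 0:
        raise ValueError("no animals")
    animal_means = [np.atleast_2d(np.asarray(a, dtype=float)).mean(axis=0)
                    for a in per_animal]
    stacked = np.vstack(animal_means)
    mean = stacked.mean(axis=0)
    n = stacked.shape[0]
    if n > 1:
        sem = stacked.std(axis=0, ddof=1) / np.sqrt(n)
        return GroupAverage(mean, sem, n, True)
    return GroupAverage(mean, np.zeros_like(mean), 1, False)
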