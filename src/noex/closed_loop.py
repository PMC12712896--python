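"""Closed-loop optogenetic stimulation logic (deterministic simulation).

Real-time tracking triggers stimulation when any part of the animal stays
inside a circular region of interest around the object for longer than a
100 ms debounce (which suppresses tracking jitter).  While occupancy
persists, a 1 Hz trigger fires, and each trigger launches a 500 ms pulse
train of 5 ms pulses at 15 Hz.  Under continuous occupancy this yields a
50% duty cycle of stimulation (one 500 ms train per second).

Conventions (the hardware chain does not pin these down): the first
trigger fires the moment the debounce elapses, subsequent triggers every
1/trigger_rate s of continuous occupancy, and re-entry restarts the
debounce; the first pulse of a train coincides with train onset
(onset-inclusive), so a 500 ms train at 15 Hz carries 8 pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .keypoints import CleanTrack

__all__ = [
    "StimConfig",
    "TriggerResult",
    "PulseTrain",
    "occupancy_trigger",
    "build_pulse_train",
    "session_duty_cycle",
]


@dataclass(frozen=True)
class StimConfig:
    roi_center: Tuple[float, float] = (15.0, 15.0)
    roi_radius: float = 7.0          # cm
    debounce_ms: float = 100.0
    trigger_rate: float = 1.0        # Hz
    train_duration_ms: float = 500.0
    pulse_rate: float = 15.0         # Hz
    pulse_width_ms: float = 5.0
    latency_ms: float = 0.0          # chain latency; 0 unless measured

    def __post_init__(self) -> None:
        if self.roi_radius <= 0 or self.trigger_rate <= 0 or self.pulse_rate <= 0:
            raise ValueError("radius and rates must be positive")
        if self.pulse_width_ms * self.pulse_rate > 1000.0:
            raise ValueError("pulses do not fit the pulse period")
        if self.train_duration_ms > 1000.0 / self.trigger_rate:
            raise ValueError("train longer than the trigger period")

    @property
    def debounce_s(self) -> float:
        return self.debounce_ms / 1000.0

    @property
    def train_duration_s(self) -> float:
        return self.train_duration_ms / 1000.0


@dataclass
class TriggerResult:
    times: np.ndarray        # s
    occupied_s: float        # total ROI occupancy over the session
    n_episodes: int


@dataclass
class PulseTrain:
    train_onsets: np.ndarray             # s
    pulse_onsets: List[np.ndarray]       # s, one array per train
    pulse_width_ms: float
    train_duration_ms: float

    @property
    def n_pulses(self) -> int:
        return int(sum(p.size for p in self.pulse_onsets))

    @property
    def light_on_s(self) -> float:
        return self.n_pulses * self.pulse_width_ms / 1000.0

    @property
    def stim_on_s(self) -> float:
        """Total time covered by trains (train-level on-time)."""
        return self.train_onsets.size * self.train_duration_ms / 1000.0


def _occupancy_episodes(track: CleanTrack, cfg: StimConfig) -> List[Tuple[float, float]]:
    """(start, end) times in s of maximal any-part-in-ROI runs; frame f
    covers [f/fps, (f+1)/fps)."""
    dists = track.distances_to(cfg.roi_center)
    inside = np.logical_or.reduce([d <= cfg.roi_radius for d in dists.values()])
    if inside.size == 0:
        return []
    padded = np.concatenate([[False], inside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(s / track.fps, e / track.fps)
            for s, e in zip(edges[::2], edges[1::2])]


def occupancy_trigger(track: CleanTrack, cfg: StimConfig) -> TriggerResult:
    """Trigger times from ROI occupancy with debounce.

    Within each continuous occupancy episode longer than the debounce,
    triggers fire at ``trigger_rate`` starting when the debounce elapses
    and stopping on ROI exit.  An episode of 90 ms at the default 100 ms
    debounce produces no trigger.
    """
    times: List[float] = []
    occupied = 0.0
    episodes = _occupancy_episodes(track, cfg)
    for start, end in episodes:
        occupied += end - start
        t = start + cfg.debounce_s + cfg.latency_ms / 1000.0
        period = 1.0 / cfg.trigger_rate
        while t < end - 1e-12:
            times.append(t)
            t += period
    return TriggerResult(np.asarray(times), occupied, len(episodes))


def build_pulse_train(trigger_times: Sequence[float], cfg: StimConfig) -> PulseTrain:
    """One train per trigger; pulses at the pulse period from train onset
    while the onset falls strictly inside the train (onset-inclusive, so
    ceil(train_duration * pulse_rate) pulses per train)."""
    t = np.sort(np.asarray(trigger_times, dtype=float))
    if t.size and np.any(np.diff(t) < cfg.train_duration_s - 1e-12):
        raise ValueError("triggers closer than the train duration: "
                         "trains would overlap")
    period = 1.0 / cfg.pulse_rate
    dur = cfg.train_duration_s
    n_pulses = int(np.ceil(dur * cfg.pulse_rate - 1e-12))
    offsets = np.arange(n_pulses) * period
    pulses = [onset + offsets for onset in t]
    return PulseTrain(train_onsets=t, pulse_onsets=pulses,
                      pulse_width_ms=cfg.pulse_width_ms,
                      train_duration_ms=cfg.train_duration_ms)


def session_duty_cycle(train: PulseTrain, occupied_s: float) -> float:
    """Fraction of ROI-occupied time covered by stimulation trains.

    With the default configuration and continuous occupancy this is 0.5
    (one 500 ms train per second of occupancy).
    """
    if occupied_s <= 0:
        raise ValueError("occupied time must be positive")
    return train.stim_on_s / occupied_s
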