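"""Synthetic sessions with known ground truth for every downstream stage.

The generators emulate the study conditions of a novel-object exploration
assay — a ~60 x 60 cm open-field arena with an object placed 15 cm from two
walls — and the recording modalities consumed by the analysis modules:

* keypoint sessions: a three-keypoint (nose, head, tail-base) trajectory
  that wanders far from the object and executes scripted approach-retreat
  bouts toward it, of tail-behind or tail-exposed type, with Gaussian
  keypoint noise and likelihood dropouts;
* Markov syllable sequences with a temperature-controlled transition matrix;
* frequency-modulated photometry (carriers at 200 and 250 Hz, 4 kHz) with
  exponential photobleaching, white noise, and dopamine-like transients at
  known times and amplitudes, plus start/end sync pulses;
* fluorescence-lifetime traces (ns) with transients on a baseline.

Every generator is deterministic under a fixed seed, and each returns a
ground-truth ledger (`BoutLog`, transient tables) that the tests use as the
oracle for recovery by the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .keypoints import PARTS, KeypointTrack
from .photometry import RawPhotometry, LifetimeSignal
from .syllables import SyllableSequence

__all__ = [
    "SimSessionConfig",
    "simulate_keypoint_session",
    "simulate_syllable_sequence",
    "temper_transition_matrix",
    "stationary_distribution",
    "stationary_bigram_distribution",
    "make_transient_log",
    "simulate_fm_photometry",
    "simulate_lifetime_trace",
]

# body geometry (cm): keypoints sit on the body axis through the centroid
NOSE_OFFSET = 2.5
HEAD_OFFSET = 1.0
TAIL_OFFSET = 2.5

_APPROACH_SPEED = 8.0      # cm/s on the approach/retreat legs
_WANDER_SPEED = 10.0       # cm/s between bouts
_STAGING_DIST = 20.0       # cm from object where a bout begins and ends
_NEAR_DIST = 3.0           # cm of closest centroid approach
_DWELL_S = 1.2             # total slow outward drift near the object
# outward drift during the dwell; steep enough that the nose-distance
# minimum at arrival stays sharp against smoothed keypoint noise
_DRIFT_SPEED = 2.0         # cm/s
_TURN_S = 0.4              # in-place turn for tail-exposed bouts
_WANDER_RADIUS = 21.0      # cm: inter-bout arcs around the object
_ARC_STEP_DEG = 40.0
# staging directions that keep the path inside a 60x60 arena with the
# object 15 cm from two walls
_THETA_RANGE = (-math.pi / 6, 2 * math.pi / 3)


@dataclass(frozen=True)
class SimSessionConfig:
    """Conditions of one simulated novel-object session."""

    arena_size: Tuple[float, float] = (60.0, 60.0)
    object_center: Tuple[float, float] = (15.0, 15.0)
    fps: float = 30.0
    duration: float = 180.0            # s
    n_bouts: int = 12
    tail_exposed_prob: float = 0.5     # per-bout type probability
    tail_exposed_fraction: float = 0.6  # designed in-radius tail-closer share
    keypoint_noise_sd: float = 0.1     # cm
    dropout_rate: float = 0.02         # per-frame likelihood dropout
    seed: int = 0
    interact_radius: float = 7.0       # used only for ground-truth labeling

    def __post_init__(self) -> None:
        w, h = self.arena_size
        if w <= 0 or h <= 0 or self.fps <= 0 or self.duration <= 0:
            raise ValueError("arena_size, fps and duration must be positive")
        ox, oy = self.object_center
        if not (0 <= ox <= w and 0 <= oy <= h):
            raise ValueError("object_center outside the arena")
        if not 0 <= self.tail_exposed_prob <= 1:
            raise ValueError("tail_exposed_prob must be in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_bouts < 0 or self.keypoint_noise_sd < 0:
            raise ValueError("n_bouts and keypoint_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# keypoint sessions
# ---------------------------------------------------------------------------

def _angle_seq(theta_a: float, theta_b: float) -> List[float]:
    """Intermediate arc angles from a to b in steps of <= _ARC_STEP_DEG."""
    step = math.radians(_ARC_STEP_DEG)
    n = max(1, int(math.ceil(abs(theta_b - theta_a) / step)))
    return [theta_a + (theta_b - theta_a) * k / n for k in range(1, n + 1)]


def _segment_frames(p0: np.ndarray, p1: np.ndarray, n: int,
                    facing: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Linear centroid motion over n frames with fixed per-frame facing."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
    centers = p0 + t * (p1 - p0)
    return centers, np.broadcast_to(facing, (n, 2)).copy()


def _turn_frames(center: np.ndarray, theta0: float, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """In-place half-turn: facing rotates by pi over n frames."""
    angles = theta0 + np.pi * np.linspace(0.0, 1.0, n, endpoint=False)
    facing = np.column_stack([np.cos(angles), np.sin(angles)])
    return np.broadcast_to(center, (n, 2)).copy(), facing


def _build_script(cfg: SimSessionConfig, rng: np.random.Generator
                  ) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Per-frame (centroid, facing) arrays plus the per-bout type draws.

    The path alternates wander arcs at _WANDER_RADIUS around the object
    with scripted bouts: a straight approach facing the object down to
    _NEAR_DIST, a slow outward drift (so the nose-distance minimum is
    unique at arrival), for tail-exposed bouts an in-place half turn timed
    to hit the designed tail-exposed fraction, and a straight retreat —
    backing out still facing the object (tail-behind) or walking away
    facing away (tail-exposed).
    """
    obj = np.asarray(cfg.object_center, dtype=float)
    fps = cfg.fps
    n_total = int(round(cfg.duration * fps))

    thetas = rng.uniform(*_THETA_RANGE, size=max(cfg.n_bouts, 1))
    bout_types = ["tail-exposed" if rng.random() < cfg.tail_exposed_prob
                  else "tail-behind" for _ in range(cfg.n_bouts)]

    def unit(theta: float) -> np.ndarray:
        return np.array([math.cos(theta), math.sin(theta)])

    centers: List[np.ndarray] = []
    facings: List[np.ndarray] = []

    def add_move(p0, p1, speed, facing_vec=None) -> np.ndarray:
        d = float(np.hypot(*(p1 - p0)))
        n = max(1, int(round(d / speed * fps)))
        if facing_vec is None:
            facing_vec = (p1 - p0) / max(d, 1e-9)
        c, f = _segment_frames(p0, p1, n, np.asarray(facing_vec, dtype=float))
        centers.append(c)
        facings.append(f)
        return p1

    # timing of the in-radius window (used to place the optional turn):
    # centroid enters the labeled window when the leading keypoint crosses
    # the interaction radius
    v = _APPROACH_SPEED
    t_in_approach = (cfg.interact_radius + NOSE_OFFSET - _NEAR_DIST) / v
    # retreat leg starts from the drifted-out distance; while walking away
    # the closest keypoint is the tail base
    drift_out = _NEAR_DIST + _DRIFT_SPEED * _DWELL_S
    t_in_retreat = max(cfg.interact_radius + TAIL_OFFSET - drift_out, 0.0) / v
    t_in_total = t_in_approach + _DWELL_S + t_in_retreat

    pos = obj + _WANDER_RADIUS * unit(thetas[0])
    if cfg.n_bouts == 0:
        # wander the far arc for the whole session
        theta = thetas[0]
        while sum(len(c) for c in centers) < n_total:
            theta_next = rng.uniform(*_THETA_RANGE)
            for th in _angle_seq(theta, theta_next):
                pos = add_move(pos, obj + _WANDER_RADIUS * unit(th),
                               _WANDER_SPEED)
            theta = theta_next
    for i in range(cfg.n_bouts):
        th = thetas[i]
        u = unit(th)
        staging = obj + _STAGING_DIST * u
        near = obj + _NEAR_DIST * u
        # approach from the wander arc via staging
        pos = add_move(pos, staging, _WANDER_SPEED)
        pos = add_move(pos, near, v, facing_vec=-u)  # facing the object
        if bout_types[i] == "tail-behind":
            # slow outward drift, then back away still facing the object
            drift_end = near + _DRIFT_SPEED * _DWELL_S * u
            pos = add_move(pos, drift_end, _DRIFT_SPEED, facing_vec=-u)
            pos = add_move(pos, staging, v, facing_vec=-u)
        else:
            t_turn_total = t_in_total + _TURN_S
            t_tail_target = cfg.tail_exposed_fraction * t_turn_total
            # tail is closer from mid-turn on: solve for the post-turn dwell
            t_post = t_tail_target - _TURN_S / 2 - t_in_retreat
            t_post = float(np.clip(t_post, 0.0, _DWELL_S))
            t_pre = _DWELL_S - t_post
            p = near
            if t_pre > 1 / fps:
                p = add_move(p, p + _DRIFT_SPEED * t_pre * u, _DRIFT_SPEED,
                             facing_vec=-u)
            n_turn = max(2, int(round(_TURN_S * fps)))
            c, f = _turn_frames(p, math.atan2(-u[1], -u[0]), n_turn)
            centers.append(c)
            facings.append(f)
            pos = p
            if t_post > 1 / fps:
                pos = add_move(pos, pos + _DRIFT_SPEED * t_post * u,
                               _DRIFT_SPEED, facing_vec=u)
            pos = add_move(pos, staging, v, facing_vec=u)  # walk away
        # wander arc toward the next bout's direction
        th_next = thetas[(i + 1) % len(thetas)] if i + 1 < cfg.n_bouts else th
        pos = add_move(pos, obj + _WANDER_RADIUS * unit(th), _WANDER_SPEED)
        for a in _angle_seq(th, th_next):
            pos = add_move(pos, obj + _WANDER_RADIUS * unit(a), _WANDER_SPEED)

    center = np.concatenate(centers, axis=0)
    facing = np.concatenate(facings, axis=0)
    if cfg.n_bouts == 0:
        # pure wander overshoots by up to one arc; trim to the session
        center = center[:n_total]
        facing = facing[:n_total]
    if center.shape[0] < n_total:
        pad = n_total - center.shape[0]
        center = np.concatenate([center, np.repeat(center[-1:], pad, axis=0)])
        facing = np.concatenate([facing, np.repeat(facing[-1:], pad, axis=0)])
    elif center.shape[0] > n_total:
        raise ValueError(
            f"duration {cfg.duration} s too short for {cfg.n_bouts} bouts: "
            f"script needs {center.shape[0] / fps:.1f} s")
    return center, facing, bout_types


def _keypoints_from_script(center: np.ndarray, facing: np.ndarray
                           ) -> Dict[str, np.ndarray]:
    return {
        "nose": center + NOSE_OFFSET * facing,
        "head": center + HEAD_OFFSET * facing,
        "tail_base": center - TAIL_OFFSET * facing,
    }


def _smooth(xy: np.ndarray, median_window: int = 5, mean_window: int = 15) -> np.ndarray:
    """The cleaning pipeline's median+mean smoothing, restated here so that
    ground truth reflects an ideal noise-free measurement processed the
    same way (the filters legitimately shift boundaries by a few frames)."""
    out = np.empty_like(xy)
    for c in range(xy.shape[1]):
        s = pd.Series(xy[:, c])
        m = s.rolling(median_window, center=True, min_periods=1).median()
        out[:, c] = m.rolling(mean_window, center=True, min_periods=1).mean().to_numpy()
    return out


def _true_bouts(clean_xy: Dict[str, np.ndarray], cfg: SimSessionConfig,
                bout_types: List[str]) -> pd.DataFrame:
    """Ground-truth bout table from the noiseless geometry, by the same
    rules the segmentation applies (restated in plain numpy)."""
    obj = np.asarray(cfg.object_center, dtype=float)
    d = {p: np.hypot(*(clean_xy[p] - obj).T) for p in clean_xy}
    any_in = ((d["nose"] <= cfg.interact_radius)
              | (d["head"] <= cfg.interact_radius)
              | (d["tail_base"] <= cfg.interact_radius))
    nt_in = ((d["nose"] <= cfg.interact_radius)
             | (d["tail_base"] <= cfg.interact_radius))
    padded = np.concatenate([[False], any_in, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    rows = []
    for idx, (s, e1) in enumerate(zip(edges[::2], edges[1::2])):
        s, e = int(s), int(e1) - 1
        nt = np.flatnonzero(nt_in[s:e + 1]) + s
        if nt.size == 0:
            continue
        enter, end = int(nt[0]), int(nt[-1]) + 1
        retreat = enter + int(np.argmin(d["nose"][enter:end]))
        run = np.arange(s, e + 1)
        tail_closer = d["tail_base"][run] < d["nose"][run]
        frac = float(tail_closer.mean())
        rows.append({
            "bout": idx,
            "true_start_frame": s,
            "true_enter_frame": enter,
            "true_retreat_start_frame": retreat,
            "true_end_frame": end,
            "true_type": bout_types[len(rows)] if len(rows) < len(bout_types) else "?",
            "true_tail_exposed_fraction": frac,
        })
    return pd.DataFrame(rows)


def simulate_keypoint_session(cfg: SimSessionConfig
                              ) -> Tuple[KeypointTrack, pd.DataFrame]:
    """Simulate one tracked session; returns the noisy track and the
    ground-truth bout log.

    The bout log records, per scripted bout, the start / enter / retreat
    start / end frames, the scripted type, and the tail-exposed fraction,
    all computed on the noiseless smoothed geometry.  Dropout frames
    receive a uniform-random corrupted position and a likelihood drawn
    uniformly below 0.9; all other frames get likelihood in [0.95, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    center, facing, bout_types = _build_script(cfg, rng)
    clean = _keypoints_from_script(center, facing)
    w, h = cfg.arena_size
    for p in clean:
        clean[p][:, 0] = np.clip(clean[p][:, 0], 0.0, w)
        clean[p][:, 1] = np.clip(clean[p][:, 1], 0.0, h)
    truth = _true_bouts({p: _smooth(clean[p]) for p in clean}, cfg, bout_types)

    n = center.shape[0]
    xy: Dict[str, np.ndarray] = {}
    lik: Dict[str, np.ndarray] = {}
    for p in PARTS:
        noisy = clean[p] + rng.normal(0.0, cfg.keypoint_noise_sd, size=(n, 2))
        drop = rng.random(n) < cfg.dropout_rate
        noisy[drop] = rng.uniform([0, 0], [w, h], size=(int(drop.sum()), 2))
        likelihood = rng.uniform(0.95, 1.0, size=n)
        likelihood[drop] = rng.uniform(0.0, 0.9, size=int(drop.sum()))
        noisy[:, 0] = np.clip(noisy[:, 0], 0.0, w)
        noisy[:, 1] = np.clip(noisy[:, 1], 0.0, h)
        xy[p] = noisy
        lik[p] = likelihood
    return KeypointTrack(xy=xy, likelihood=lik, fps=cfg.fps), truth


# ---------------------------------------------------------------------------
# syllable sequences
# ---------------------------------------------------------------------------

def _check_stochastic(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("rows must be non-negative and sum to 1")
    return m


def temper_transition_matrix(matrix: np.ndarray, temperature: float) -> np.ndarray:
    """Row-wise power 1/temperature, renormalized.  Temperature above 1
    flattens rows toward uniform; below 1 sharpens them."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = _check_stochastic(matrix)
    with np.errstate(divide="ignore"):
        powed = np.where(m > 0, m ** (1.0 / temperature), 0.0)
    return powed / powed.sum(axis=1, keepdims=True)


def stationary_distribution(matrix: np.ndarray, n_iter: int = 2000) -> np.ndarray:
    """Stationary row vector by power iteration from uniform."""
    m = _check_stochastic(matrix)
    pi = np.full(m.shape[0], 1.0 / m.shape[0])
    for _ in range(n_iter):
        nxt = pi @ m
        if np.max(np.abs(nxt - pi)) < 1e-14:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def stationary_bigram_distribution(matrix: np.ndarray,
                                   temperature: float = 1.0) -> np.ndarray:
    """Analytic stationary law of ordered bigrams of the tempered chain:
    pi(a, b) = pi_a P(a, b)."""
    t = temper_transition_matrix(matrix, temperature)
    pi = stationary_distribution(t)
    return pi[:, None] * t


def simulate_syllable_sequence(transition_matrix: np.ndarray, n_frames: int,
                               temperature: float = 1.0, seed: int = 0,
                               **metadata) -> SyllableSequence:
    """Sample a syllable sequence from the tempered Markov chain, with the
    initial state drawn from its stationary distribution."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    t = temper_transition_matrix(transition_matrix, temperature)
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(t)
    cdf = np.cumsum(t, axis=1)
    labels = np.empty(n_frames, dtype=int)
    labels[0] = int(rng.choice(t.shape[0], p=pi))
    draws = rng.random(n_frames - 1)
    state = labels[0]
    for i in range(1, n_frames):
        state = int(np.searchsorted(cdf[state], draws[i - 1], side="right"))
        state = min(state, t.shape[0] - 1)
        labels[i] = state
    return SyllableSequence(labels=labels, **metadata)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def make_transient_log(onsets: Sequence[float], amplitudes: Sequence[float],
                       widths: Sequence[float]) -> pd.DataFrame:
    """Ground-truth transient table: onset (s; the transient's center),
    amplitude (modulation depth or ns) and Gaussian width (s, sd)."""
    log = pd.DataFrame({"onset": np.asarray(onsets, dtype=float),
                        "amplitude": np.asarray(amplitudes, dtype=float),
                        "width": np.asarray(widths, dtype=float)})
    if not np.all(np.isfinite(log.to_numpy())):
        raise ValueError("transient parameters must be finite")
    if np.any(log["width"] <= 0):
        raise ValueError("widths must be positive")
    return log


def _transient_waveform(t: np.ndarray, transients: Optional[pd.DataFrame]) -> np.ndarray:
    wave = np.zeros_like(t)
    if transients is None or len(transients) == 0:
        return wave
    for _, row in transients.iterrows():
        wave += row["amplitude"] * np.exp(-0.5 * ((t - row["onset"]) / row["width"]) ** 2)
    return wave


def simulate_fm_photometry(duration: float, fs: float = 4000.0,
                           carriers: Optional[Dict[str, float]] = None,
                           transients: Optional[pd.DataFrame] = None,
                           baseline: float = 1.0,
                           bleach_tau: float = np.inf,
                           noise_sd: float = 0.0,
                           ref_amplitude: float = 1.0,
                           sync_margin: float = 0.25,
                           seed: int = 0) -> RawPhotometry:
    """Two-carrier FM trace with photobleaching, transients and sync pulses.

    The signal-carrier modulation depth is
    ``baseline * exp(-t/bleach_tau) * (1 + sum of Gaussian transients)``;
    the reference carrier has constant depth.  TTL sync pulses (20 ms) are
    embedded on the companion channel ``sync_margin`` s after session start
    and before session end.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(duration * fs))
    if abs(n - duration * fs) > 1e-9:
        raise ValueError("duration * fs must be integral")
    carriers = dict(carriers) if carriers else dict(
        signal=200.0, reference=250.0)
    if max(carriers.values()) * 2 >= fs:
        raise ValueError("carriers must be below Nyquist")
    if transients is not None and len(transients):
        if (transients["onset"].min() < 0
                or transients["onset"].max() > duration):
            raise ValueError("transient onset outside the session")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    bleach = np.exp(-t / bleach_tau) if np.isfinite(bleach_tau) else np.ones(n)
    depth = baseline * bleach * (1.0 + _transient_waveform(t, transients))
    x = (depth * np.sin(2 * np.pi * carriers["signal"] * t)
         + ref_amplitude * np.sin(2 * np.pi * carriers["reference"] * t))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    sync = np.zeros(n)
    pulse = max(1, int(round(0.020 * fs)))
    for t0 in (sync_margin, duration - sync_margin):
        i = int(round(t0 * fs))
        sync[i:i + pulse] = 1.0
    return RawPhotometry(signal=x, sync=sync, fs=fs, carriers=carriers)


def simulate_lifetime_trace(duration: float, fs: float = 200.0,
                            baseline: float = 2.6,
                            transients: Optional[pd.DataFrame] = None,
                            noise_sd: float = 0.0,
                            seed: int = 0) -> LifetimeSignal:
    """Fluorescence-lifetime trace (ns): constant baseline plus Gaussian
    transients (amplitudes in ns) and white noise."""
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if transients is not None and len(transients):
        if (transients["onset"].min() < 0
                or transients["onset"].max() > duration):
            raise ValueError("transient onset outside the session")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    values = baseline + _transient_waveform(t, transients)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return LifetimeSignal(values=values, rate=fs)
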