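"""Keypoint-trajectory cleaning and novel-object interaction bouts.

A session is tracked with three body parts (nose, head, tail base).  Frames
whose pose likelihood falls below 0.9 are trimmed and linearly interpolated,
and trajectories are smoothed with a 5-frame moving median followed by a
15-frame moving average.  An *interaction bout* is a maximal run of frames
in which any body part lies within the 7 cm interaction radius of the object
center; within a bout, each frame is classified by whether the nose or the
tail base is closer to the object (Euclidean distance), which splits bouts
into *tail-behind* (nose always closer: risk-assessed exploration) versus
*tail-exposed* episodes.  The start of retreat is the in-bout frame of
minimal nose-object distance.

Coordinates are in cm, origin at the arena's lower-left corner, y up;
frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PARTS",
    "ArenaConfig",
    "KeypointTrack",
    "CleanTrack",
    "InteractionBout",
    "ExplorationMetrics",
    "RetreatSpeed",
    "preprocess_track",
    "segment_interactions",
    "classify_tail_exposure",
    "exploration_metrics",
    "retreat_speed",
    "segment_and_classify",
]

PARTS = ("nose", "head", "tail_base")


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and calibration.

    ``interact_radius`` is the interaction radius around the object center
    (default 7 cm); ``px_to_cm`` scales raw pixel tracks into cm and is 1.0
    for tracks already in cm.
    """

    width: float = 60.0
    height: float = 60.0
    object_center: Tuple[float, float] = (15.0, 15.0)
    interact_radius: float = 7.0
    fps: float = 30.0
    px_to_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.fps <= 0:
            raise ValueError("width, height and fps must be positive")
        if self.interact_radius <= 0:
            raise ValueError("interact_radius must be positive")
        ox, oy = self.object_center
        if not (0 <= ox <= self.width and 0 <= oy <= self.height):
            raise ValueError("object_center must lie within the arena")


@dataclass
class KeypointTrack:
    """Raw per-frame keypoints: ``xy[part]`` is (n_frames, 2) in cm,
    ``likelihood[part]`` in [0, 1]."""

    xy: Dict[str, np.ndarray]
    likelihood: Dict[str, np.ndarray]
    fps: float

    def __post_init__(self) -> None:
        lengths = {len(self.xy[p]) for p in self.xy}
        lengths |= {len(self.likelihood[p]) for p in self.likelihood}
        if len(lengths) != 1:
            raise ValueError("all parts must have equal frame counts")
        for p, lik in self.likelihood.items():
            lik = np.asarray(lik)
            if np.any((lik < 0) | (lik > 1)):
                raise ValueError(f"likelihood out of [0, 1] for part {p!r}")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.xy.values())))


@dataclass
class CleanTrack:
    """Cleaned keypoints; ``interpolated[part]`` flags frames whose position
    was trimmed (likelihood below threshold) and filled by interpolation."""

    xy: Dict[str, np.ndarray]
    interpolated: Dict[str, np.ndarray]
    fps: float

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.xy.values())))

    def distances_to(self, point: Tuple[float, float]) -> Dict[str, np.ndarray]:
        p = np.asarray(point, dtype=float)
        return {part: np.hypot(*(self.xy[part] - p).T) for part in self.xy}


@dataclass
class InteractionBout:
    """One approach-retreat episode.

    ``frames`` are the bout's in-radius frames (any body part within the
    interaction radius).  ``closer_part`` (parallel to ``frames``) labels
    each in-radius frame 'nose' or 'tail'; it is filled by
    :func:`classify_tail_exposure`.
    """

    start_frame: int
    enter_frame: int
    retreat_start_frame: int
    end_frame: int
    frames: np.ndarray
    closer_part: Optional[np.ndarray] = None
    bout_type: Optional[str] = None
    tail_exposed_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.start_frame <= self.enter_frame
                <= self.retreat_start_frame <= self.end_frame):
            raise ValueError("bout frames must satisfy "
                             "start <= enter <= retreat_start <= end")


@dataclass(frozen=True)
class ExplorationMetrics:
    interacting_time: float       # s
    tail_exposure_fraction: float  # of in-radius frames
    n_interactions: int
    mean_retreat_speed: float     # cm/s


@dataclass(frozen=True)
class RetreatSpeed:
    cm_per_s: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _moving(series: np.ndarray, window: int, how: str) -> np.ndarray:
    s = pd.Series(series).rolling(window, center=True, min_periods=1)
    return (s.median() if how == "median" else s.mean()).to_numpy()


def preprocess_track(raw: KeypointTrack, likelihood_threshold: float = 0.9,
                     median_window: int = 5, mean_window: int = 15) -> CleanTrack:
    """Trim low-likelihood frames, interpolate, and smooth.

    Frames with likelihood < ``likelihood_threshold`` are replaced by linear
    interpolation between the flanking valid frames (nearest valid value at
    the session edges); each coordinate is then passed through a centered
    moving median (default 5 frames) followed by a centered moving average
    (default 15 frames), with windows shrunk to the valid range at the
    session boundaries.
    """
    xy_out: Dict[str, np.ndarray] = {}
    flags: Dict[str, np.ndarray] = {}
    frames = None
    for part, pos in raw.xy.items():
        pos = np.asarray(pos, dtype=float)
        lik = np.asarray(raw.likelihood[part], dtype=float)
        valid = lik >= likelihood_threshold
        if valid.sum() < 2:
            raise ValueError(
                f"part {part!r}: only {int(valid.sum())} frames at or above "
                f"likelihood {likelihood_threshold}; cannot interpolate")
        if frames is None:
            frames = np.arange(pos.shape[0])
        filled = pos.copy()
        for c in range(2):
            filled[~valid, c] = np.interp(frames[~valid], frames[valid],
                                          pos[valid, c])
        smoothed = np.column_stack([
            _moving(_moving(filled[:, c], median_window, "median"),
                    mean_window, "mean")
            for c in range(2)
        ])
        xy_out[part] = smoothed
        flags[part] = ~valid
    return CleanTrack(xy=xy_out, interpolated=flags, fps=raw.fps)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]


def segment_interactions(track: CleanTrack, arena: ArenaConfig) -> List[InteractionBout]:
    """Segment maximal runs of any-part-in-radius frames into bouts.

    Within each run, ``enter_frame`` is the first frame with nose or tail
    base in radius, ``end_frame`` the first frame after the last such frame
    (the end of retreat: neither nose nor tail in radius), and
    ``retreat_start_frame`` the earliest frame of minimal nose-object
    distance between entry and end.  Runs where neither nose nor tail ever
    enters the radius cannot be anchored and are discarded.  Bouts are not
    merged: a single-frame exit splits two bouts.
    """
    if track.n_frames == 0:
        return []
    dists = track.distances_to(arena.object_center)
    in_radius = {p: d <= arena.interact_radius for p, d in dists.items()}
    any_in = np.logical_or.reduce([in_radius[p] for p in track.xy])
    nose_or_tail = in_radius["nose"] | in_radius["tail_base"]

    bouts: List[InteractionBout] = []
    for s, e in _runs(any_in):
        nt = np.flatnonzero(nose_or_tail[s:e + 1]) + s
        if nt.size == 0:
            continue
        enter = int(nt[0])
        end = int(nt[-1]) + 1
        seg = dists["nose"][enter:end]
        retreat_start = enter + int(np.argmin(seg))
        bouts.append(InteractionBout(
            start_frame=s, enter_frame=enter,
            retreat_start_frame=retreat_start, end_frame=end,
            frames=np.arange(s, e + 1)))
    return bouts


def classify_tail_exposure(bout: InteractionBout, track: CleanTrack,
                           arena: ArenaConfig) -> InteractionBout:
    """Label each in-radius frame by the closer of nose vs tail base.

    Returns a copy of the bout with ``closer_part``, ``bout_type`` and
    ``tail_exposed_fraction`` filled.  A bout is *tail-behind* iff the nose
    is closer at every in-radius frame (distance ties count as nose).
    """
    if bout.frames.size == 0:
        raise ValueError("bout has no in-radius frames")
    if bout.frames[-1] >= track.n_frames:
        raise ValueError("bout frames extend beyond the track")
    obj = np.asarray(arena.object_center, dtype=float)
    d_nose = np.hypot(*(track.xy["nose"][bout.frames] - obj).T)
    d_tail = np.hypot(*(track.xy["tail_base"][bout.frames] - obj).T)
    tail_closer = d_tail < d_nose
    labels = np.where(tail_closer, "tail", "nose")
    fraction = float(np.mean(tail_closer))
    return replace(bout, closer_part=labels,
                   bout_type="tail-exposed" if fraction > 0 else "tail-behind",
                   tail_exposed_fraction=fraction)


def segment_and_classify(track: CleanTrack, arena: ArenaConfig) -> List[InteractionBout]:
    return [classify_tail_exposure(b, track, arena)
            for b in segment_interactions(track, arena)]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def retreat_speed(bout: InteractionBout, track: CleanTrack,
                  arena: ArenaConfig) -> RetreatSpeed:
    """Mean nose speed (cm/s) over the retreat, from retreat start to the
    end of the bout.  A single-frame retreat is degenerate: speed 0."""
    last = min(bout.end_frame, track.n_frames - 1)
    if last <= bout.retreat_start_frame:
        return RetreatSpeed(0.0, degenerate=True)
    path = track.xy["nose"][bout.retreat_start_frame:last + 1]
    step = np.hypot(*np.diff(path, axis=0).T)
    return RetreatSpeed(float(step.mean() * track.fps), degenerate=False)


def exploration_metrics(bouts: Sequence[InteractionBout], track: CleanTrack,
                        arena: ArenaConfig) -> ExplorationMetrics:
    """Session-level exploration summary.

    ``interacting_time`` is the summed in-radius duration over bouts;
    ``tail_exposure_fraction`` pools tail-closer frames over all in-radius
    frames of the session; ``mean_retreat_speed`` averages over
    non-degenerate retreats.
    """
    if not bouts:
        return ExplorationMetrics(0.0, 0.0, 0, 0.0)
    classified = [b if b.closer_part is not None
                  else classify_tail_exposure(b, track, arena) for b in bouts]
    total_frames = sum(b.frames.size for b in classified)
    tail_frames = sum(int(np.sum(b.closer_part == "tail")) for b in classified)
    speeds = [retreat_speed(b, track, arena) for b in classified]
    ok = [s.cm_per_s for s in speeds if not s.degenerate]
    return ExplorationMetrics(
        interacting_time=total_frames / track.fps,
        tail_exposure_fraction=tail_frames / total_frames,
        n_interactions=len(classified),
        mean_retreat_speed=float(np.mean(ok)) if ok else 0.0,
    )
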