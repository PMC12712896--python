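"""Behavioral-syllable statistics downstream of motion sequencing.

Syllable labels (one integer per video frame, produced upstream by an
AR-HMM segmentation of depth video) are consumed as input.  This module
computes usage frequencies and enrichment between groups, the cumulative-90%
syllable selection rule, joint bigram transition distributions (including
self-transitions), their Shannon entropy in bits, rolling (quintile)
entropy, and near- vs far-from-object usage conditioning on the keypoint
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .keypoints import ArenaConfig, CleanTrack
from .stats import bonferroni, mann_whitney_u

__all__ = [
    "SyllableSequence",
    "TransitionDistribution",
    "usage_frequencies",
    "usage_vector",
    "select_top_syllables",
    "enrichment_test",
    "transition_distribution",
    "shannon_entropy",
    "quintile_entropy",
    "near_object_usage",
]


@dataclass
class SyllableSequence:
    """Per-frame integer syllable labels with session metadata."""

    labels: np.ndarray
    session_id: Optional[str] = None
    group: Optional[str] = None           # e.g. hungry / sated
    session_type: Optional[str] = None    # e.g. empty-arena / object

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise ValueError("empty syllable sequence")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class TransitionDistribution:
    """Joint probability over ordered syllable bigrams, diagonal included."""

    matrix: np.ndarray
    frame_range: Tuple[int, int]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("entries must be a probability distribution")


def _n_syllables(seqs: Sequence[SyllableSequence],
                 n_syllables: Optional[int]) -> int:
    if n_syllables is not None:
        return int(n_syllables)
    return int(max(s.labels.max() for s in seqs)) + 1


# ---------------------------------------------------------------------------
# usage
# ---------------------------------------------------------------------------

def usage_vector(seq: SyllableSequence, n_syllables: Optional[int] = None) -> np.ndarray:
    """Within-session usage: fraction of frames per syllable."""
    k = _n_syllables([seq], n_syllables)
    counts = np.bincount(seq.labels, minlength=k).astype(float)
    return counts / counts.sum()


def usage_frequencies(seqs: Sequence[SyllableSequence], scope: str = "session_type",
                      n_syllables: Optional[int] = None) -> pd.DataFrame:
    """Pooled usage frequencies, normalized within each scope.

    ``scope`` is a metadata attribute of the sequences ('session_type',
    'group' or 'session_id'); frames are pooled across all sequences sharing
    a scope value and divided by the scope's total frame count, so
    frequencies sum to 1 within each scope.
    """
    if not seqs:
        raise ValueError("no sequences")
    k = _n_syllables(seqs, n_syllables)
    rows = []
    keys = sorted({getattr(s, scope) for s in seqs}, key=str)
    for key in keys:
        members = [s for s in seqs if getattr(s, scope) == key]
        counts = np.zeros(k)
        for s in members:
            counts += np.bincount(s.labels, minlength=k)
        if counts.sum() == 0:
            raise ValueError(f"scope {key!r} has no frames")
        freq = counts / counts.sum()
        rows.extend({"scope": key, "syllable": i, "frequency": freq[i]}
                    for i in range(k))
    return pd.DataFrame(rows)


def select_top_syllables(usage: Sequence[float], cumulative: float = 0.9) -> np.ndarray:
    """Smallest prefix of usage-sorted syllables reaching the cumulative
    frequency cutoff (the rule that kept 58 of 100 syllables at 90%)."""
    if not 0 < cumulative <= 1:
        raise ValueError("cumulative must be in (0, 1]")
    u = np.asarray(usage, dtype=float)
    order = np.argsort(-u, kind="stable")
    csum = np.cumsum(u[order])
    if cumulative >= 1:
        n_keep = int(np.sum(u > 0))
    else:
        n_keep = int(np.searchsorted(csum, cumulative * u.sum() - 1e-12)) + 1
    return np.sort(order[:n_keep])


def enrichment_test(usage_a: np.ndarray, usage_b: np.ndarray,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-syllable two-sided Mann-Whitney U between per-animal usage
    vectors (animals x syllables), Bonferroni-corrected over syllables."""
    a = np.atleast_2d(np.asarray(usage_a, dtype=float))
    b = np.atleast_2d(np.asarray(usage_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 animals per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must cover the same syllables")
    results = [mann_whitney_u(a[:, s], b[:, s]) for s in range(a.shape[1])]
    p_raw = np.array([r.p for r in results])
    p_adj = bonferroni(p_raw)
    return pd.DataFrame({
        "syllable": np.arange(a.shape[1]),
        "U": [r.statistic for r in results],
        "p_raw": p_raw,
        "p_bonferroni": p_adj,
        "significant": p_adj < alpha,
        "direction": [r.direction for r in results],
    })


# ---------------------------------------------------------------------------
# transitions and entropy
# ---------------------------------------------------------------------------

def transition_distribution(seq: SyllableSequence,
                            frame_range: Optional[Tuple[int, int]] = None,
                            n_syllables: Optional[int] = None) -> TransitionDistribution:
    """Joint bigram distribution pi(a, b) over consecutive label pairs,
    self-transitions included."""
    start, stop = frame_range if frame_range is not None else (0, len(seq))
    labels = seq.labels[start:stop]
    if labels.size < 2:
        raise ValueError("need at least 2 frames to count transitions")
    k = _n_syllables([seq], n_syllables)
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    return TransitionDistribution(counts / counts.sum(), (start, stop))


def shannon_entropy(dist, base: float = 2.0) -> float:
    """Shannon entropy H = -sum_i pi_i log(pi_i), in bits by default,
    with 0 log 0 := 0.  Accepts a TransitionDistribution or any array of
    probabilities."""
    p = dist.matrix if isinstance(dist, TransitionDistribution) else np.asarray(dist, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(base))


def quintile_entropy(seq: SyllableSequence, n_bins: int = 5,
                     n_syllables: Optional[int] = None) -> np.ndarray:
    """Rolling entropy: the session split into ``n_bins`` contiguous spans
    (earlier spans take the remainder frames, lengths differ by <= 1), a
    separate bigram distribution per span, entropy of each in bits."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    bounds = np.array_split(np.arange(len(seq)), n_bins)
    if any(b.size < 2 for b in bounds):
        raise ValueError("sequence too short for the requested bins")
    k = _n_syllables([seq], n_syllables)
    return np.array([
        shannon_entropy(transition_distribution(
            seq, (int(b[0]), int(b[-1]) + 1), n_syllables=k))
        for b in bounds
    ])


# ---------------------------------------------------------------------------
# near-object conditioning
# ---------------------------------------------------------------------------

def near_object_usage(seq: SyllableSequence, track: CleanTrack,
                      arena: ArenaConfig,
                      n_syllables: Optional[int] = None) -> pd.DataFrame:
    """Usage computed separately over in-radius (any body part within the
    interaction radius) and out-of-radius frames.  Both columns sum to 1."""
    if len(seq) != track.n_frames:
        raise ValueError("sequence and track must be frame-aligned")
    dists = track.distances_to(arena.object_center)
    near = np.logical_or.reduce([d <= arena.interact_radius
                                 for d in dists.values()])
    if not near.any():
        raise ValueError("no in-radius frames; near-object usage undefined")
    k = _n_syllables([seq], n_syllables)
    out = {}
    for name, mask in (("near_freq", near), ("far_freq", ~near)):
        counts = np.bincount(seq.labels[mask], minlength=k).astype(float)
        out[name] = counts / counts.sum() if counts.sum() else np.full(k, np.nan)
    return pd.DataFrame({"syllable": np.arange(k), **out})
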