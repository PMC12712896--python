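"""Track cleaning, bout segmentation and exploration metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_clean_track
from noex import keypoints as kp
from noex.synthetic import SimSessionConfig, simulate_keypoint_session


def make_raw(positions, likelihood=None, fps=30.0):
    nose = np.asarray(positions["nose"], dtype=float)
    n = len(nose)
    xy = {p: np.asarray(positions.get(p, nose), dtype=float).copy()
          for p in kp.PARTS}
    lik = {p: (np.ones(n) if likelihood is None
               else np.asarray(likelihood.get(p, np.ones(n)), dtype=float))
           for p in kp.PARTS}
    return kp.KeypointTrack(xy=xy, likelihood=lik, fps=fps)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_low_likelihood_frame_interpolated_to_midpoint():
    pos = np.array([[0.0, 0.0], [99.0, -99.0], [2.0, 2.0]])
    lik = {"nose": np.array([1.0, 0.2, 1.0])}
    raw = make_raw({"nose": pos}, likelihood=lik)
    clean = kp.preprocess_track(raw, median_window=1, mean_window=1)
    assert np.allclose(clean.xy["nose"][1], [1.0, 1.0])
    assert clean.interpolated["nose"][1]
    assert not clean.interpolated["nose"][0]


def test_constant_track_is_fixed_point():
    pos = np.full((40, 2), 12.3)
    clean = kp.preprocess_track(make_raw({"nose": pos}))
    assert np.allclose(clean.xy["nose"], 12.3)
    # idempotence: running the cleaned values through again changes nothing
    again = kp.preprocess_track(make_raw({"nose": clean.xy["nose"]}))
    assert np.allclose(again.xy["nose"], clean.xy["nose"])


def test_spike_removed_and_matches_filter_oracle():
    # 30-frame linear ramp with one 10 cm spike
    t = np.arange(30, dtype=float)
    pos = np.column_stack([t, 2 * t])
    pos[14] += 10.0
    clean = kp.preprocess_track(make_raw({"nose": pos}))

    def oracle(x, med, mean):
        n = len(x)
        m = np.array([np.median(x[max(0, i - med // 2):i + med // 2 + 1])
                      for i in range(n)])
        return np.array([np.mean(m[max(0, i - mean // 2):i + mean // 2 + 1])
                         for i in range(n)])

    for c in range(2):
        assert np.allclose(clean.xy["nose"][:, c],
                           oracle(pos[:, c], 5, 15), atol=1e-12)
    assert abs(clean.xy["nose"][14, 0] - 14.0) < 1.0  # spike suppressed


def test_part_entirely_below_threshold_rejected():
    pos = np.zeros((10, 2))
    lik = {"head": np.full(10, 0.1)}
    with pytest.raises(ValueError, match="head"):
        kp.preprocess_track(make_raw({"nose": pos}, likelihood=lik))


def test_leading_trailing_dropouts_filled_with_nearest_valid():
    pos = np.array([[9.0, 9.0], [1.0, 1.0], [2.0, 2.0], [9.0, 9.0]])
    lik = {"nose": np.array([0.0, 1.0, 1.0, 0.0])}
    clean = kp.preprocess_track(make_raw({"nose": pos}, likelihood=lik),
                                median_window=1, mean_window=1)
    assert np.allclose(clean.xy["nose"][0], [1.0, 1.0])
    assert np.allclose(clean.xy["nose"][-1], [2.0, 2.0])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def linear_pass_track(closest=3.0, far=30.0, n=201):
    """Nose travels a straight line past the object (collapsed body)."""
    obj = np.array([15.0, 15.0])
    x = np.linspace(-far, far, n)
    pos = obj + np.column_stack([x, np.full(n, closest)])
    return make_clean_track({"nose": pos})


def test_far_trajectory_yields_no_bouts(arena):
    track = make_clean_track({"nose": np.full((100, 2), 50.0)})
    assert kp.segment_interactions(track, arena) == []


def test_single_crossing_yields_one_bout_with_countable_time(arena):
    track = linear_pass_track()
    bouts = kp.segment_interactions(track, arena)
    assert len(bouts) == 1
    obj = np.array(arena.object_center)
    inside = np.hypot(*(track.xy["nose"] - obj).T) <= arena.interact_radius
    assert bouts[0].frames.size == inside.sum()
    metrics = kp.exploration_metrics(bouts, track, arena)
    assert metrics.interacting_time == pytest.approx(inside.sum() / track.fps)


def test_one_frame_exit_splits_bouts(arena):
    # inside -> one far frame -> inside again: two bouts, not one
    inside, outside = (15.0, 15.0), (50.0, 50.0)
    pos = np.array([inside] * 10 + [outside] + [inside] * 10)
    track = make_clean_track({"nose": pos})
    assert len(kp.segment_interactions(track, arena)) == 2


def test_enlarging_radius_never_decreases_interacting_time():
    cfg = SimSessionConfig(n_bouts=5, seed=11, duration=120.0)
    raw, _ = simulate_keypoint_session(cfg)
    clean = kp.preprocess_track(raw)
    times = []
    for r in (4.0, 7.0, 10.0, 14.0):
        arena_r = kp.ArenaConfig(interact_radius=r)
        bouts = kp.segment_interactions(clean, arena_r)
        times.append(kp.exploration_metrics(bouts, clean, arena_r).interacting_time)
    assert np.all(np.diff(times) >= 0)


# ---------------------------------------------------------------------------
# tail-exposure classification
# ---------------------------------------------------------------------------

def two_part_track(nose_pos, tail_pos):
    return make_clean_track({"nose": nose_pos, "head": nose_pos,
                             "tail_base": tail_pos})


def test_nose_always_closer_is_tail_behind(arena):
    n = 20
    nose = np.full((n, 2), (14.0, 15.0))   # 1 cm from the object
    tail = np.full((n, 2), (10.0, 15.0))   # 5 cm away
    track = two_part_track(nose, tail)
    bouts = kp.segment_and_classify(track, arena)
    assert len(bouts) == 1
    assert bouts[0].bout_type == "tail-behind"
    assert bouts[0].tail_exposed_fraction == 0.0


def test_half_frames_tail_closer_gives_fraction_half(arena):
    n = 40
    nose = np.full((n, 2), (14.0, 15.0))
    tail = np.full((n, 2), (10.0, 15.0))
    nose[n // 2:], tail[n // 2:] = (10.0, 15.0), (14.0, 15.0)
    bouts = kp.segment_and_classify(two_part_track(nose, tail), arena)
    assert bouts[0].tail_exposed_fraction == pytest.approx(0.5)
    assert bouts[0].bout_type == "tail-exposed"


def test_distance_tie_labels_nose(arena):
    n = 10
    nose = np.full((n, 2), (14.0, 15.0))
    tail = np.full((n, 2), (16.0, 15.0))  # both exactly 1 cm away
    bouts = kp.segment_and_classify(two_part_track(nose, tail), arena)
    assert bouts[0].bout_type == "tail-behind"


def test_classify_rejects_bout_without_frames(arena):
    track = make_clean_track({"nose": np.full((5, 2), 15.0)})
    bout = kp.InteractionBout(0, 0, 0, 1, frames=np.array([], dtype=int))
    with pytest.raises(ValueError):
        kp.classify_tail_exposure(bout, track, arena)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_metrics_empty_session_all_zero(arena):
    track = make_clean_track({"nose": np.full((10, 2), 50.0)})
    m = kp.exploration_metrics([], track, arena)
    assert (m.interacting_time, m.tail_exposure_fraction, m.n_interactions) \
        == (0.0, 0.0, 0)


def test_metrics_pool_two_bouts(arena):
    """3 s + 5 s of interaction at 30 fps with 60 of 240 tail-closer frames
    -> (8 s, 0.25, 2)."""
    near_nose, near_tail = (14.0, 15.0), (10.0, 15.0)
    far = (50.0, 50.0)
    nose, tail = [], []
    nose += [near_nose] * 90; tail += [near_tail] * 90        # bout 1: 3 s
    nose += [far] * 30; tail += [far] * 30                    # gap
    nose += [near_nose] * 90; tail += [near_tail] * 90        # bout 2: 5 s
    nose += [near_tail] * 60; tail += [near_nose] * 60        # tail closer
    nose += [far] * 30; tail += [far] * 30
    track = two_part_track(np.array(nose), np.array(tail))
    bouts = kp.segment_and_classify(track, arena)
    m = kp.exploration_metrics(bouts, track, arena)
    assert m.interacting_time == pytest.approx(8.0)
    assert m.tail_exposure_fraction == pytest.approx(0.25)
    assert m.n_interactions == 2


def test_retreat_speed_constant_straight_line(arena):
    # nose leaves the object at 5 cm/s along +x
    fps = 30.0
    n = 61
    x = 15.0 + 1.0 + 5.0 * np.arange(n) / fps
    pos = np.column_stack([x, np.full(n, 15.0)])
    track = make_clean_track({"nose": pos}, fps=fps)
    bouts = kp.segment_interactions(track, arena)
    assert len(bouts) == 1
    speed = kp.retreat_speed(bouts[0], track, arena)
    assert not speed.degenerate
    assert speed.cm_per_s == pytest.approx(5.0)


def test_retreat_speed_stationary_nose_degenerate(arena):
    track = make_clean_track({"nose": np.full((10, 2), (14.0, 15.0))})
    bout = kp.InteractionBout(0, 0, 9, 9, frames=np.arange(10))
    speed = kp.retreat_speed(bout, track, arena)
    assert speed.cm_per_s == 0.0 and speed.degenerate


# ---------------------------------------------------------------------------
# simulator-oracle recovery (single session; the multi-seed suite lives in
# the acceptance tests)
# ---------------------------------------------------------------------------

def test_scripted_session_recovered_within_tolerance(arena):
    cfg = SimSessionConfig(n_bouts=12, keypoint_noise_sd=0.2,
                           dropout_rate=0.02, seed=42)
    raw, log = simulate_keypoint_session(cfg)
    clean = kp.preprocess_track(raw)
    bouts = kp.segment_and_classify(clean, arena)
    assert len(bouts) == len(log) == 12
    for bout, (_, row) in zip(bouts, log.iterrows()):
        assert abs(bout.start_frame - row.true_start_frame) <= 2
        assert abs(bout.end_frame - row.true_end_frame) <= 2
        assert abs(bout.retreat_start_frame - row.true_retreat_start_frame) <= 2
        assert abs(bout.tail_exposed_fraction
                   - row.true_tail_exposed_fraction) <= 0.05
        assert bout.bout_type == row.true_type
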