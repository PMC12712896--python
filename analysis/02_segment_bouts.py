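"""Clean the simulated keypoint session, segment interaction bouts, and
compare the recovered bouts and exploration metrics against ground truth.

Reads results/session/ (run 01_simulate_session.py first); writes
results/bouts.csv and results/exploration_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from noex import io
from noex import keypoints as kp

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    track = io.read_dlc_csv(ROOT / "session" / "keypoints.csv", fps=30.0)
    truth = pd.read_csv(ROOT / "session" / "bout_log.csv")
    arena = kp.ArenaConfig()

    clean = kp.preprocess_track(track)
    n_interp = sum(flags.sum() for flags in clean.interpolated.values())
    print(f"cleaned {track.n_frames} frames; "
          f"{n_interp} part-frames interpolated (<90% likelihood)")

    bouts = kp.segment_and_classify(clean, arena)
    rows = []
    for b in bouts:
        speed = kp.retreat_speed(b, clean, arena)
        rows.append({
            "start_frame": b.start_frame, "enter_frame": b.enter_frame,
            "retreat_start_frame": b.retreat_start_frame,
            "end_frame": b.end_frame, "bout_type": b.bout_type,
            "tail_exposed_fraction": b.tail_exposed_fraction,
            "retreat_speed_cm_s": speed.cm_per_s,
        })
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "bouts.csv", index=False)

    assert len(bouts) == len(truth), "bout count mismatch against truth"
    errs = (table[["start_frame", "retreat_start_frame", "end_frame"]].to_numpy()
            - truth[["true_start_frame", "true_retreat_start_frame",
                     "true_end_frame"]].to_numpy())
    print(f"recovered {len(bouts)} bouts; max boundary error "
          f"{abs(errs).max()} frames; max tail-fraction error "
          f"{(table.tail_exposed_fraction - truth.true_tail_exposed_fraction).abs().max():.3f}")

    m = kp.exploration_metrics(bouts, clean, arena)
    pd.DataFrame([m.__dict__]).to_csv(ROOT / "exploration_metrics.csv",
                                      index=False)
    print(f"interacting time {m.interacting_time:.1f} s over "
          f"{m.n_interactions} interactions; tail exposure "
          f"{m.tail_exposure_fraction:.2f}; mean retreat speed "
          f"{m.mean_retreat_speed:.1f} cm/s")


if __name__ == "__main__":
    main()
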