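"""Generate one ground-truthed synthetic session of every modality.

Writes, under results/session/: a DeepLabCut-dialect keypoint CSV with its
bout log, a syllable-label CSV, an FM photometry HDF5 trace with its
transient log, and a lifetime trace CSV.  These files feed the downstream
analysis scripts.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from noex import io
from noex import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "session"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = syn.SimSessionConfig(n_bouts=12, keypoint_noise_sd=0.2,
                               dropout_rate=0.02, seed=SEED)
    track, bout_log = syn.simulate_keypoint_session(cfg)
    io.write_dlc_csv(track, OUT / "keypoints.csv")
    bout_log.to_csv(OUT / "bout_log.csv", index=False)
    print(f"keypoints: {track.n_frames} frames at {cfg.fps} fps, "
          f"{len(bout_log)} scripted bouts "
          f"({(bout_log.true_type == 'tail-exposed').sum()} tail-exposed)")

    rng = np.random.default_rng(SEED)
    base = rng.dirichlet(np.ones(30) * 0.6, size=30)
    seq = syn.simulate_syllable_sequence(base, track.n_frames, seed=SEED,
                                         session_id="demo", group="hungry",
                                         session_type="object")
    io.write_syllable_csv(seq, OUT / "syllables.csv")
    np.savetxt(OUT / "syllable_transition_matrix.csv", base, delimiter=",")
    print(f"syllables: {len(seq)} frames over {base.shape[0]} syllables")

    onsets = 5.0 + 8.0 * np.arange(20)
    amps = np.round(np.linspace(0.2, 0.4, 20), 3)
    rng.shuffle(amps)
    tlog = syn.make_transient_log(onsets, amps, np.full(20, 0.15))
    raw = syn.simulate_fm_photometry(float(onsets[-1] + 5), transients=tlog,
                                     bleach_tau=1200.0, noise_sd=0.02,
                                     seed=SEED)
    io.write_photometry_h5(raw, OUT / "photometry.h5")
    tlog.to_csv(OUT / "transient_log.csv", index=False)
    print(f"photometry: {raw.signal.size} samples at {raw.fs:.0f} Hz, "
          f"{len(tlog)} transients")

    lt = syn.simulate_lifetime_trace(60.0, fs=200.0, transients=syn.make_transient_log(
        [15.0, 30.0, 45.0], [0.05] * 3, [0.4] * 3), noise_sd=0.01, seed=SEED)
    pd.DataFrame({"lifetime_ns": lt.values}).to_csv(
        OUT / "lifetime.csv", index=False)
    print(f"lifetime: {lt.values.size} samples at {lt.rate:.0f} Hz")


if __name__ == "__main__":
    main()
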