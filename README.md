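# noex — novel-object exploration analysis

`noex` is an analysis toolkit for open-field novel-object exploration
experiments in mice, built for studies that combine pose tracking,
behavioral-syllable sequencing, fiber photometry of striatal dopamine, and
closed-loop optogenetics. It implements the desk-computable half of such a
study — everything downstream of the recordings — together with synthetic
generators that produce ground-truthed stand-ins for every recording
modality, so the whole pipeline is testable without animal data.

It is aimed at behavioral-neuroscience labs analyzing approach–avoid
behavior toward a novel object (a risk/exploration conflict: hungry animals
explore more and less cautiously than sated ones) with time-series readouts
of dopamine release in the tail of striatum (TOS).

## What it computes

**Interaction bouts from keypoints** (`noex.keypoints`). Nose / head /
tail-base trajectories (DeepLabCut-dialect CSV) are cleaned by trimming
frames below 90% likelihood, linear interpolation, a 5-frame moving median
and a 15-frame moving average. An interaction bout is a maximal run of
frames with any body part within the 7 cm interaction radius of the object
center. Within a bout, each frame is labeled by whether the nose or the
tail base is closer to the object (Euclidean distance): a bout where the
nose is always closer is *tail-behind* (risk-assessed posture); any
tail-closer frame makes it *tail-exposed*. Retreat starts at the frame of
minimal nose–object distance. Session metrics: interacting time, normalized
tail-exposure time, number of interactions, retreat speed.

**Syllable statistics** (`noex.syllables`). Per-frame syllable labels (from
an upstream AR-HMM segmentation, e.g. MoSeq) are summarized as usage
frequencies (normalized per session type), the cumulative-90% selection
rule, per-syllable group enrichment (two-sided Mann-Whitney U with
Bonferroni correction), and sequencing stereotypy via the Shannon entropy

&nbsp;&nbsp;&nbsp;&nbsp;H = −Σᵢ πᵢ log₂ πᵢ  (bits)

of the joint distribution π over ordered syllable bigrams, self-transitions
included; rolling entropy splits a session into quintiles.

**FM photometry** (`noex.photometry`). Two LED channels are sinusoidally
modulated (470 nm at 200 Hz, 565 nm at 250 Hz) and digitized at 4 kHz.
Demodulation takes short-time spectral power at the band nearest each
carrier (spectrogram, 216-sample window, 108-sample overlap → one output
sample per 27 ms); slow photobleaching is removed with 30 s rolling
z-scores. Video frames are synchronized via start/end TTL pulses, signals
are aligned to behavioral events (approach start, retreat start, retreat
end), and the retreat response is the baseline-subtracted mean from 1 s
before to 1 s after retreat start. Group traces average within animal, then
across animals. Fluorescence-lifetime traces (ns) follow the same path
after moving-average downsampling to 10 Hz.

**Closed-loop stimulation logic** (`noex.closed_loop`). ROI occupancy with
a 100 ms debounce drives a 1 Hz trigger; each trigger launches a 500 ms
train of 5 ms pulses at 15 Hz — a 50% duty cycle under continuous
occupancy.

**Exact small-sample statistics** (`noex.stats`). Mann-Whitney U, Wilcoxon
signed-rank, Friedman with Kendall's W, Bonferroni, Pearson/Spearman — with
p-values from full enumeration of the permutation null at small n (U:
n₁+n₂ ≤ 16; Wilcoxon: n ≤ 20; Spearman: n ≤ 8), midrank tie handling
included.

**Synthetic data** (`noex.synthetic`). Scripted keypoint sessions in a
60 × 60 cm arena (object 15 cm from two walls) with configurable bout
count, tail-exposure probability, keypoint noise and likelihood dropouts,
plus a ground-truth bout log; tempered Markov syllable sequences;
two-carrier FM photometry with photobleaching, noise and dopamine-like
transients at known times; lifetime traces. All deterministic under a seed.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on synthetic
sessions and write tables under `results/`:

```bash
python analysis/01_simulate_session.py
python analysis/02_segment_bouts.py
python analysis/06_cohort_comparison.py
```

prints (abridged):

```
keypoints: 5400 frames at 30.0 fps, 12 scripted bouts (9 tail-exposed)
recovered 12 bouts; max boundary error 1 frames; max tail-fraction error 0.011
interacting time 34.0 s over 12 interactions; tail exposure 0.46; mean retreat speed 5.3 cm/s

hungry vs sated (Mann-Whitney U, two-sided):
  interacting_time: U=72, p=0.0006258 *** (higher in hungry)
  tail_exposure_fraction: U=72, p=0.0006306 *** (higher in hungry)
  retreat_response: U=0, p=0.0006355 *** (lower in hungry)
```

The 12 scripted bouts are recovered with frame-level boundary accuracy, and
the simulated hungry cohort (n=9) shows more interaction, more tail
exposure and smaller retreat-associated dopamine responses than the sated
cohort (n=8) — the designed effect directions, detected by the exact
two-sided tests.

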