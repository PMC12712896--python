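# Methods

This note documents the models, conventions and design choices behind
`noex`, in the spirit of the methods appendices of simulation/analysis
packages: what each stage assumes, which knobs matter, and what the
synthetic generators do and do not emulate.

## Keypoint cleaning and bout segmentation

**Cleaning.** Pose estimators emit per-frame (x, y, likelihood) for nose,
head and tail base. Frames with likelihood < 0.9 are treated as missing and
filled by linear interpolation between the flanking valid frames; leading or
trailing missing frames, which have no flank on one side, take the nearest
valid value. Each coordinate then passes a centered 5-frame moving median
(despiking) and a centered 15-frame moving average (smoothing). Windows
shrink to the valid range at session edges — no padding is invented. For
even window lengths the extra sample sits on the early side (the pandas
centering convention); cleaning a constant track is the identity.

**Segmentation.** Interacting frames are those with *any* of the three
body parts within the interaction radius (default 7 cm) of the object
center; bouts are maximal runs of interacting frames, and a single-frame
exit splits two bouts (no merge rule). Within a run, entry is the first
frame with nose or tail base in radius and the bout ends at the first frame
after which neither is in radius; a run in which only the head ever enters
the radius cannot be anchored and is discarded. Retreat starts at the
earliest frame of minimal nose–object distance between entry and end.
Frame-level classification uses nose vs tail base only (the radius test
uses all three parts — an intentional asymmetry of the interaction
definition); distance ties label the frame "nose", biasing toward the
conservative tail-behind call. The bout start is the first frame of the
interacting run containing the entry frame.

Coordinates are cm with origin at the arena's lower-left corner, y up,
0-based frames. The pixel scale (`px_to_cm`) and camera rate (`fps`) are
calibration inputs, never hard-coded; defaults assume 30 fps.

**Retreat speed** is the mean frame-to-frame nose displacement times fps
over [retreat start, bout end]; single-frame retreats are degenerate and
report 0 with a flag.

## Syllable statistics

Transition structure is summarized by the *joint* distribution over ordered
bigrams (including self-transitions), not row-conditional entropies:
π(a,b) is the fraction of consecutive frame pairs labeled (a,b). Entropy is
H = −Σ π log₂ π in bits (0·log 0 := 0); the choice of base is a convention
(all comparisons are base-invariant) and is exposed as a parameter. For a
K-syllable session 0 ≤ H ≤ 2 log₂ K, with equality at the uniform bigram
law, and H is invariant under syllable relabeling. Rolling entropy splits a
session into five contiguous spans whose lengths differ by at most one
frame, earlier spans taking the remainder.

Usage frequencies normalize pooled counts within a scope (session type for
group summaries; within-animal for the per-animal vectors used in tests).
The cumulative-90% rule keeps the smallest usage-sorted prefix of syllables
reaching 90% of frames. Enrichment between groups runs a two-sided
Mann-Whitney U per syllable on per-animal usage, Bonferroni-corrected over
the syllables tested. Near-object usage conditions on the same any-part
interaction radius as bout segmentation.

When entropies are averaged across sessions of an animal, sessions get
equal weight regardless of length.

## FM photometry

The model of the recorded trace is
`depth(t)·sin(2π·200·t) + ref·sin(2π·250·t) + ε`, with
`depth(t) = baseline · exp(−t/τ_bleach) · (1 + Σ transients)` and ε white.
Demodulation computes a spectrogram (scipy) with a 216-sample window and
108-sample overlap at 4 kHz — a 108-sample hop, hence one output sample per
27 ms and output length ⌊(N − 216)/108⌋ + 1 — and extracts the frequency
band nearest each carrier. The window taper defaults to the spectrogram
default Tukey(0.25) and is configurable; with the default geometry the
measured crosstalk of a step on one carrier into the other channel is
≈ 0.14%, comfortably below the 1% separability requirement. Because
neither carrier falls exactly on a bin center, nearest-bin power carries a
small deterministic ripple that repeats every few hops; it averages out in
event-aligned means and is absorbed by z-scoring.

Detrending is a centered 30 s rolling z-score (shrunk at edges, sample
std; zero-variance windows map to 0). It can be applied to the raw trace
before demodulation and is applied again to the demodulated power when
z-scored output is requested. On recordings shorter than the z window the
window shrinks to the recording.

Synchronization assumes exactly one start and one end TTL pulse (rising
edge at half peak); frame times are interpolated linearly between them, and
each frame maps to the nearest demodulated sample. Event alignment snips a
common relative-time lattice around each event and drops (and counts)
events whose window is truncated.

**Responses.** The retreat response is the per-trial mean of the
baseline-subtracted signal over [−1, +1] s around retreat start. The
baseline is the per-trial mean over a configurable pre-event window
(default [−3, −1] s; `None` disables it); a windowed *peak* is available
behind a flag, but the mean is canonical so the intensity and lifetime
responses use the same operator. Trial decay is summarized by means over
consecutive strata of 10 trials, the final partial stratum retained and
flagged. Group traces average within animal across trials, then across
animals (equal animal weights regardless of trial counts), with SEM across
animals. Lifetime traces are downsampled by non-overlapping block means to
10 Hz (20 Hz for fast assays); non-integer decimation ratios floor the
block size with a warning.

## Closed-loop stimulation

Occupancy is any body part within the ROI radius; a frame covers
[f/fps, (f+1)/fps). Episodes shorter than the 100 ms debounce trigger
nothing; otherwise the first trigger fires when the debounce elapses and
further triggers every 1 s of continuous occupancy, stopping at ROI exit;
re-entry restarts the debounce. Each trigger launches a 500 ms train whose
first pulse coincides with train onset (onset-inclusive; the hardware phase
is not specified, so this convention is documented and configurable),
giving ⌈0.5 · 15⌉ = 8 pulses of 5 ms. Chain latency defaults to 0 and is
configurable. The duty cycle is reported over occupied time; continuous
occupancy yields exactly trigger-rate × train-duration = 50%. Triggers
faster than one train length would overlap and are rejected.

## Exact nonparametric tests

U is oriented on the first group, U = #{aᵢ > bⱼ} + ½·ties, so it ranges
over [0, n₁n₂] (both orientations sum to n₁n₂). Exact two-sided p-values
come from full enumeration of the permutation null — group labelings for U
(n₁+n₂ ≤ 16), sign flips for Wilcoxon (n ≤ 20, computed by convolution
over half-integer midranks), permutations for Spearman (n ≤ 8) — with
two-sidedness defined by deviation from the null mean at least as large as
observed. Beyond these fixed thresholds the standard tie-corrected
asymptotics (scipy) take over. Wilcoxon drops zero differences before
ranking (the common convention). Friedman uses within-row midranks with the
standard tie correction; all-constant rows carry no rank information and
return χ² = 0, W = 0, p = 1. Kendall's W = χ²/(n(k−1)). Degenerate
all-equal group comparisons return p = 1.

## Synthetic generators

The keypoint generator scripts a centroid + facing-direction trajectory:
wander arcs ~21 cm from the object alternate with bouts consisting of a
straight 8 cm/s approach (facing the object, nose leading) down to 3 cm, a
1.2 s outward drift at 2 cm/s, and a straight retreat. Tail-behind bouts
back away still facing the object; tail-exposed bouts insert a 0.4 s
in-place half-turn whose timing is solved so the tail-closer share of
in-radius time hits the configured target (default 0.6), then walk away.
Keypoints sit on the body axis (nose +2.5 cm, head +1 cm, tail base
−2.5 cm from the centroid). Gaussian position noise is added per frame;
dropout frames get a uniform-random arena position and likelihood below
0.9 (stressing the trim-and-interpolate path), other frames likelihood in
[0.95, 1].

The drift away from the closest approach is deliberately steep (2 cm/s) so
the nose-distance minimum defining retreat start is sharp; a flatter dwell
makes the argmin ill-conditioned against smoothed keypoint noise.

**Ground truth.** The bout log records boundaries, type and tail-exposed
fraction computed from the *noiseless* geometry after the same
median+mean smoothing the cleaning stage applies (restated independently in
the generator). Truth therefore reflects an ideal noise-free measurement
processed identically, and recovery tests measure robustness to noise and
dropout rather than filter delay. At the default conditions (0.2 cm noise,
2% dropout) 20-seed sweeps recover all bouts with boundaries within ±2
frames and tail fractions within ±0.02; at the stressed end of the envelope
(0.3 cm, 5% dropout) occasional dropout runs spanning a radius crossing
push single boundaries to ±3 frames.

Syllable sequences are sampled from a row-stochastic matrix tempered by a
row-wise power 1/T and renormalized (T > 1 flattens toward uniform, T < 1
sharpens), with the initial state drawn from the tempered chain's
stationary law; the analytic stationary bigram law π_a·P(a,b) serves as the
convergence oracle. FM photometry adds Gaussian-bump transients
(multiplicative on the signal-carrier depth), exponential photobleaching
and white noise, and embeds 20 ms sync pulses 0.25 s from each session end.
Lifetime traces are a baseline (default 2.6 ns) plus additive transients in
ns. Every generator is bit-reproducible under its seed.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: mouse biomechanics (rigid body axis, scripted
speeds), posture-dependent pose-estimation error (noise is isotropic and
homoscedastic), hemodynamic or motion artifacts in photometry (the additive
two-carrier model is clean), correlated syllable-keypoint dynamics, and
session-scale behavioral drift other than photobleaching.

## Study conditions for the cohort simulation

The end-to-end cohort study compares n=9 "hungry" vs n=8 "sated" animals.
The real group differences arise from recordings that are not reproduced
here, so the effect sizes are a generator design choice, fixed once:
hungry sessions script 12±1 bouts with tail-exposure probability 0.9 and
retreat-transient modulation depth 0.25; sated sessions 6±1 bouts, 0.35,
and 0.5. Directions mirror the study's findings (hungry: more interaction,
more tail exposure, smaller dopamine transients at retreat); magnitudes are
chosen to give clearly separated cohorts so the replicated detection rate
measures pipeline correctness, not statistical power at a marginal effect.
Photometry sessions are 40 s with 8 transients per animal (a scale chosen
to keep replicated simulations fast), with bleach τ = 120 s and noise
0.02.

## Numerical choices and known limitations

* Amplitude ordering of z-scored intensity responses degrades under strong
  photobleaching: a multiplicative decay reorders transient amplitudes
  faster than rolling z-scores can renormalize them. Transient-recovery
  checks therefore run at mild bleach (τ ≫ session length); this mirrors
  the real-world rationale for lifetime-based photometry, whose readout is
  bleach-insensitive.
* Nearest-bin demodulation quantizes the carrier to the closest of the
  18.5 Hz-wide spectrogram bins; 250 Hz falls exactly between two bins and
  the lower one is taken deterministically.
* Exact-test thresholds (16/20/8) are fixed, never data-dependent; exact
  null distributions are memoized on the rank multiset.
* The quintile remainder rule, tie rules (nose on distance ties, earliest
  frame on retreat-start ties), and the onset-inclusive pulse convention
  are deterministic tie-breaks chosen for reproducibility and documented
  where they appear.
* Likelihood-trimmed frames at session edges take nearest-valid values;
  a body part with fewer than two valid frames is rejected with a
  diagnostic rather than guessed.
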