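# Methods

## The model

Resting-state EEG is described as a sequence of *microstates*: intervals of
80–120 ms during which the scalp potential field keeps one quasi-stable
topography before switching to another. `microstate_lab` implements the
canonical four-class (A–D) analysis of this process:

1. **GFP and peak maps.** The global field power
   `GFP(t) = sqrt(mean_i (v_i(t) − v̄(t))²)` (population SD across the
   average-referenced montage) measures instantaneous field strength.
   Topographies at local GFP maxima — where the signal-to-noise ratio of
   the field is highest — are the clustering input.
2. **T-AAHC clustering.** Topographic atomize-and-agglomerate hierarchical
   clustering starts from singleton clusters and repeatedly dissolves the
   cluster contributing least global explained variance
   (`Σ_t (GFP_t · r(map_t, centroid))²` over its members), reassigning each
   freed map to the surviving cluster with the highest `|r|`, until K = 4
   clusters remain. Similarity is the absolute spatial Pearson correlation:
   for spontaneous EEG a map and its polarity reversal are the same state.
   Centroids are first principal eigenvectors of their member maps
   (sign-fixed deterministically), which is polarity-invariant and free of
   the order dependence a sign-aligned mean would have; on separated
   clusters the two agree to |r| > 0.999.
3. **Two-level template building.** Per participant × condition, T-AAHC on
   that dataset's peak maps yields individual templates; the individual
   templates of each group × condition cell are pooled (unit-normalized,
   equal weight) and clustered again into group maps. Group maps are sorted
   against a normative A–D reference by exhaustive evaluation of all K!
   label permutations (maximizing Σ|r|) with polarity aligned to the
   reference.
4. **Backfitting and parameters.** Every sample of the analysis epochs is
   labeled with the group map it correlates with most strongly in absolute
   value — all samples, no temporal smoothing, ties to the lowest class
   index. From the segmentation we compute, per class: GEV
   (`Σ_t (GFP_t·r_t)² / Σ_t GFP_t²` restricted to the class's samples),
   mean duration (ms), frequency (run onsets/s), coverage (time share),
   mean GFP (µV), and the zero-diagonal transition matrix with a
   chi-square against the coverage-implied independent null.
5. **Statistics.** Per parameter × class, a 2×2 mixed ANOVA (between:
   group; within: eye condition) with partial η² and retrospective
   "observed power" (noncentral-F with λ = F·df1 — a monotone transform of
   p reported for comparability with common software, not a design-stage
   power estimate). Significant interactions are decomposed into four
   simple-effect contrasts (paired t within group, two-sample t within
   condition) at Bonferroni α = 0.05/4 = 0.0125. Psychometric covariates
   are related to microstate parameters by Pearson correlation after a
   log(x+1) transform, Bonferroni-corrected over the declared 4-test
   family.

## Run-statistic conventions

Runs touching an epoch boundary have unobserved true length; duration and
frequency therefore exclude them by default (`include_truncated=False`),
while coverage — a pure time share — always uses every sample. In
include-truncated mode the identity `coverage = frequency × duration`
holds exactly; with exclusion it holds approximately for runs short
relative to the 2 s epoch. A class with no qualifying run reports a
missing duration (NaN), never 0.

## Preprocessing

Stages mirror a standard resting-state protocol and its constants: (i)
resample to 125 Hz (zero-phase FIR anti-alias at 0.4·target, Kaiser β=8,
then polyphase resampling), (ii) zero-phase Butterworth band-pass 2–20 Hz
plus 60 Hz notch (Q=30), (iii) 2 s epochs with per-channel baseline
removal, (iv) artifact flagging, (v) Perrin spherical-spline interpolation
of bad channels (m=4, 50 Legendre terms, λ=1e-8 ridge; exact for
constants, good channels untouched, refuses >25% bad channels), (vi)
average reference. Analysis uses the first 10 artifact-free epochs in
temporal order (20 s).

Proprietary artifact detection plus manual inspection is not reproducible;
it is replaced by an explicit deterministic rule: an epoch is rejected
when >10% of channels exceed 200 µV peak-to-peak; a channel within a kept
epoch is interpolated when it alone exceeds 200 µV or is flat (<0.5 µV
p-p). The rule is monotone in its threshold, and both thresholds are
configuration keys.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: two groups
(ASD-like, TD-like; 13 each), two conditions (EC, EO), 10 × 2 s epochs per
condition at the 125 Hz analysis rate on a 32-channel unit-sphere montage
(128 available). Per dataset:

* a hidden semi-Markov sequence draws run lengths from a gamma law
  (shape 4; right-skewed, positive, no heavy tail) with per-class mean
  durations, and successor states from a zero-diagonal transition matrix
  (uniform by default);
* the emitted frame is the class template scaled by |N(1, 0.2²)| times a
  GFP scale (µV), plus additive noise: temporally pink (1/f), spatially
  smoothed with a Gaussian great-circle kernel, scaled so template RMS /
  noise RMS equals the programmed SNR (default 2);
* the sequence is generated continuously and then cut into epochs, so
  boundary-truncated runs occur exactly as in real epoched data;
* per participant, templates are perturbed (spatial |r| to canon ≈ 0.97)
  and durations and GFP carry lognormal subject factors (σ = 0.10 and
  0.15), giving the ANOVA a realistic subject variance component; scalar
  covariates (age, IQ, SRS, RBS-R-like totals) are drawn per group.

Default cell parameters (per-class durations, per-state GFP) follow
published descriptive statistics for children's resting-state microstates
in the emulated design, so the default cohort is the study-like condition;
`recovery_design()` and `effect_design()` are controlled variants for
validation (distinct durations spanning 60–100 ms; a single programmed
group × condition duration effect).

### Canonical template geometry

The analytic A–D maps realise the textbook orientations: A and B are the
±45° frontal–occipital diagonals (`x±y`), D a Gaussian bump slightly
anterior of the vertex. C is an anterior–posterior *gradient over the
superior scalp that reverses at the inferior rim* (`y·(z−0.3)`) rather
than a pure `y` dipole: the pure dipole lies exactly in the span of A and
B (A+B ∝ y), which would make the four classes linearly degenerate and
indistinguishable at any finite SNR; the rim reversal also matches the
broad, non-dipolar structure of empirical class-C maps. All pairwise
|r| ≤ 0.32 on the default montage.

### Noise spatial scale

The smoothing kernel width is 0.4 rad. Wider kernels concentrate the
noise in the very smoothest spatial modes — at 0.6 rad, ~78% of the
average-referenced noise variance lies inside the 4-D template subspace,
i.e. the "background" becomes template-shaped signal and the programmed
SNR loses its meaning. At 0.4 rad neighbouring electrodes remain strongly
correlated (defeating naive per-channel artifact thresholds) while about
half the noise variance stays outside the template subspace.

### What the generator does not model

Eye-blink/EMG artifact morphology (artifact tests inject amplitude spikes
only), topographic non-stationarity within a run, amplitude cross-fades at
state transitions, volume-conduction-correlated background with its own
dipolar structure, and recording-session effects. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the stated
generative assumptions, not performance on arbitrary real EEG.

## Known bias: duration under noise

Sample-wise argmax backfitting with no temporal smoothing fragments true
runs wherever noise flips a single label: at SNR 2 the per-sample error
rate is ~0.5–1% and mean durations are biased low by roughly
`p_err × run_length` — a few percent for 60–70 ms classes up to ~10–13%
for 85–100 ms dipolar classes. This bias is intrinsic to the standard
analysis (real studies measure durations on exactly such segmentations)
and is documented rather than corrected; the recovery study verifies it
stays within ±15% under the study conditions.

## Numerical choices and tie-breaks

* GFP peaks: strict local maxima, epoch edges excluded, plateaus count
  once at their first sample; optional minimum separation keeps the larger
  peak.
* T-AAHC atomization ties: fewer members, then lower cluster id.
* Backfit ties: lowest class index; constant frames inherit the previous
  label (class 0 at epoch start) and are counted as degenerate.
* Sorting: exhaustive over all 4! = 24 permutations — the definition, not
  an approximation.
* Mixed ANOVA requires complete cases (both conditions per participant);
  participants missing a condition are dropped with a logged warning, no
  imputation.
* Zero-variance degenerate statistics: all-equal ANOVA data gives F = 0;
  zero-variance zero-mean t contrasts give t = 0, p = 1.
* EDF writing quantizes to 16 bits over a symmetric per-channel physical
  range (error ≤ half a quantization step); reading validates header
  integrity and fails closed on truncated files.

## Problem sizes of the validation studies

Noise-free identifiability uses 1 participant × 10 epochs; parameter
recovery the full 26 × 2 × 10-epoch cohort at SNR 2; effect detection 200
replicates (and 1000 null replicates) of the generator's ground-truth
state sequences at 5 epochs per condition — the statistical decision rule
is identical, and the full EEG chain is already exercised by the recovery
study. These sizes make the whole validation reproducible on a laptop in
a few minutes.

## Design choices on genuinely open points

* Backfitting uses |r| with no minimum-correlation rejection, and group
  maps are built per group × condition from pooled *individual templates*
  (two-level clustering); a `shared_maps` flag pools all cells for
  sensitivity analyses.
* GEV is computed over all samples (not GFP peaks only).
* The normative reference for A–D sorting is the analytic canonical set —
  a synthetic stand-in, since published normative maps are not
  redistributable data.
* The online acquisition filter (0.1–100 Hz) is not modeled; the offline
  2–20 Hz band dominates it.
* Synthetic cohorts are emitted at the 125 Hz analysis rate and are not
  re-filtered by the pipeline: the state signal is piecewise-stationary by
  construction and temporal filtering would smear exactly the run
  boundaries that recovery is measured against. The resample/filter stages
  are validated by their own tests and by the EDF path at 1000 Hz.
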