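# Methods

`natfreq` maps each brain voxel's *natural frequency* — the peak
frequency of the voxel's most representative oscillatory pattern — from
source-level time series, and identifies individuals by correlating
those maps across two instances of data. This note documents the model
assumptions, the numerical conventions, and the design choices made
where the procedure was genuinely open.

## Pipeline

### Spectral decomposition

Each voxel's signal is divided by its standard deviation across time
(beamformed source estimates have depth-dependent amplitude; only
spectral *shape* should matter downstream). A Hanning-tapered sliding
window Fourier transform is then computed in 200-ms steps on a
61-bin log-spaced axis from 1.7 to 34.5 Hz (bin *i* =
1.7·(34.5/1.7)^(i/60)). The window length adapts to frequency — 5
cycles per bin, i.e. 0.5 s at 10 Hz and ≈2.94 s at 1.7 Hz — and
10 cycles at the lowest frequency (10/1.7 ≈ 5.88 s, displayed as 5.8 s)
are trimmed from both ends of every artifact-free segment before the
first window is placed, so no window ever touches a segment edge.

Numerical conventions, chosen here because the procedure leaves them
open:

* Window length in samples is `round(fs·5/f)` forced odd, so the taper
  is symmetric about the centre sample.
* The Fourier coefficient is a direct complex-exponential projection at
  exactly the bin frequency (bin frequencies are not DFT-aligned for
  arbitrary window lengths).
* The taper is scaled to unit energy and power carries an additional
  2/L factor. Under this convention a unit-amplitude sinusoid yields
  the same peak power at every frequency (cross-frequency
  comparability), while the white/1-over-f noise floor is multiplied by
  f — which is what visibly attenuates the aperiodic 1/f component in
  the cycle-adaptive spectra relative to a fixed-window periodogram.
* Window centres start at `segment_start + trim` and advance in fixed
  steps; for a single segment of length L the window count is
  `floor((L − 2·trim)/step) + 1`.

### Whole-group clustering

Single-window spectra (150 per voxel and participant, sampled uniformly
without replacement from the *first* part/session only — training on
second-instance data would bias the later identification) are pooled
across the cohort and clustered with spherical k-means: rows
unit-normalised, cosine distance `1 − cos∠(a,b)` (amplitude-invariant),
centroid update = unit-normalised mean of the assigned rows, which is
the minimiser of summed cosine distance. k = 25, 5 replicates from
distinct random-row initialisations, up to 200 iterations; the
replicate with the lowest total distance wins. An empty cluster is
re-seeded with the point farthest from its current centroid.
Assignment ties break to the lowest centroid index for determinism.

Each centroid is annotated with its spectral peaks: strict interior
local maxima (runs of equal values collapse to their first bin;
endpoint bins are never peaks) whose prominence is at least 5% of the
centroid's maximum. The prominence floor is this package's resolution
of an otherwise under-specified definition: without it, roundoff-scale
ripple on the flat aperiodic background qualifies as "peaks", and a
spurious sub-Hz ripple peak can even demote a centroid's genuine
oscillatory peak to an apparent harmonic. With it, background-only
centroids are peakless and therefore disregarded — a spectral peak is
the evidence of genuine oscillatory activity. For two
peaks, a harmonic pair keeps only the fundamental; otherwise each peak
receives weight 0.5. The harmonic test accepts any integer multiple
m ≥ 2 with |f₂ − m·f₁| strictly below the 1-Hz tolerance; the strict
inequality keeps the canonical boundary case (7 and 22 Hz against
3×7 = 21 Hz) non-harmonic, as intended. Centroids with more than two
peaks (not covered by the two-peak rule) drop harmonics of the lowest
peak and keep the two largest-amplitude survivors at weight 0.5 each;
the event is logged.

### Single-subject maps

All available windows (not just the training sample) are classified
into the fixed clusters; per voxel, the fraction assigned to each
cluster is z-scored *across voxels* (ddof = 1), yielding the relative
presence of each cluster's peak frequency. Presence is spread onto a
10×-upsampled log-frequency axis ((61−1)·10 + 1 = 601 points, same
endpoints): each peaked cluster deposits `weight · z` at its peak
frequency, clusters sharing a frequency accumulate, and the sparse
profile is interpolated linearly in log-frequency through the populated
peak frequencies with constant extrapolation outside their span.
Linear-in-log interpolation is the simplest scheme consistent with the
upsampled spacing of the axis; the exact upsampling scheme is a design
choice of this package.

Smoothing respects abrupt spatial transitions between natural
frequencies: for each voxel, the presence profiles of the voxel and all
neighbours within 1.5 cm are tested per fine bin with a one-sample
t-test against zero (one-sided, H₁: mean > 0, matching the directional
null; sd uses ddof = 1, consistent with the t reference distribution).
The bin with the highest t is the voxel's natural frequency; if even
that bin's p exceeds 0.05, the voxel is missing (NaN). Degenerate
neighbourhoods with identical positive rows (sd = 0, mean > 0) are
treated as p → 0 and selected; max-t ties break to the lowest
frequency; a voxel with fewer than two usable rows is missing.

### Fingerprinting

Kendall's tau-b (tie-corrected — the discrete fine-frequency grid makes
maps heavily tied) is computed between every first-instance map and
every second-instance map over pairwise-complete voxels (positions
missing in either map are dropped per pair). Row-wise matching: each
first-instance map picks the most correlated second-instance map;
accuracy = % of self-matches. Per subject, `mu_others`/`sigma_others`
pool the off-diagonal entries of the subject's row *and* column
(2(N−1) values), and

* identifiability I_self = tau_self − mu_others,
* differentiability D_self = (tau_self − mu_others)/sigma_others.

Uncertainty: a 10,000-iteration subject-level bootstrap of the
accuracy (percentile 95% CI). A resampled participant counts as
correct when its best match is *any copy of itself*: duplicates drawn
by the resampling carry identical correlation columns, so identity, not
column position, defines a correct match — under position matching a
duplicated subject's second copy could never match itself and the CI
would systematically exclude the point estimate.

Significance: a 10,000-iteration permutation null that relabels the
second-instance maps and re-runs the matching; reported are the highest
permuted accuracy and p = (1 + #{perm ≥ observed})/(n_perm + 1)
(valid Monte-Carlo convention). Under a uniform relabelling the
expected number of correct matches is exactly 1 (fixed points of a
random permutation), independent of cohort size — a useful closed-form
check.

Group statistics: paired t (tau_self vs mu_others), Welch t of I and D
for target- vs non-target-matched subjects, Pearson correlation of
between-session interval with tau_self, Welch t of elapsed days for
target vs non-target matches, and a per-map Kolmogorov–Smirnov check
against a fitted normal (the non-Gaussianity of the maps is the reason
for preferring Kendall over Pearson correlation between maps).

### Voxel contribution

For each voxel, the natural frequencies of the voxel and its 1.5-cm
neighbourhood are shuffled across participants in the second-instance
maps — an independent uniform permutation per voxel in the
neighbourhood, with missing values travelling with their subject — and
the cohort-mean identifiability is recomputed. ΔI = permuted − original,
averaged over `repeats` shuffles (default 10; a single shuffle is a
noisy estimate of the same quantity). More negative ΔI marks voxels
whose neighbourhood carries more individual-specific information.

## Synthetic cohort

The underlying study is empirical and specifies no generative model;
the simulator is a stand-in built to exercise every stage with known
ground truth. It emulates:

* a base field of natural frequencies ramping 8→16 Hz along the mean of
  two grid axes (the medial→lateral and posterior→anterior
  increasing-frequency gradients of cortical oscillations);
* subject-specific deviations: white Gaussian fields smoothed with a
  Gaussian kernel (FWHM = 3 × voxel spacing, so individual features are
  locally coherent at the 1.5-cm smoothing scale), rescaled to SD
  `subject_sd` (default 0.5 Hz), identical across a subject's sessions
  — this is the fingerprint;
* per-session frequency jitter (`session_jitter_sd`, default 0.1 Hz,
  drawn per voxel);
* bursty oscillations: sinusoids amplitude-modulated by rectified
  low-pass-filtered noise (cutoff = `burst_rate`, default 1 Hz,
  normalised to unit mean) — the clustering must see varied
  single-window spectra, as real alpha/beta activity waxes and wanes;
* a 1/f^χ aperiodic background (χ default 1), generated by spectral
  shaping of white noise (FFT gain f^(−χ/2)), scaled so that
  oscillation RMS = `snr` × background RMS (default snr 1);
* session 2 elapsed days drawn uniformly from 0–1700 days, matching
  the span over which fingerprints are tested for time-robustness.

It does **not** emulate: sensor physics, field spread or source
leakage (voxel noise is independent), artifacts (segments default to
one clean interval), spatially correlated noise, multiple oscillators
per voxel, or realistic anatomy (the grid is a full cube). Passing
recovery and fingerprinting tests therefore demonstrates correctness of
the *pipeline* under a favourable, known generative process — not
performance on real recordings.

## Problem sizes for the test suite

End-to-end checks run two 12-subject cohorts (6×6×6 grid = 216 voxels,
150-s sessions at 200 Hz, snr 1): one with `subject_sd = 0` (recovery
of the planted gradient and behaviour of the permutation null) and one
with `subject_sd = 0.5` Hz (fingerprinting power). The contribution
contrast uses maps synthesised directly from planted fields (12
subjects, 5×5×5 grid), since the contribution analysis consumes maps,
not time series. These sizes were chosen once as the smallest cohorts
at which the planted effects are comfortably detectable on one CPU.

## Known limitations

* The harmonic rule is fully specified only for one or two peaks; the
  >2-peak path is a documented extension and is logged when taken.
* Spectral sampling with replacement (voxels with fewer windows than
  the quota) slightly reweights duplicated windows.
* Kendall tau on pairwise-complete voxels means different map pairs may
  use different voxel subsets when missingness varies.
* The t-test smoothing treats neighbourhood voxels as independent
  samples; spatially correlated presence inflates the effective t. The
  selection step only ranks bins, so this mainly affects the
  missing-value threshold.
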