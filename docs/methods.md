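# Methods

`hgmap` implements a non-invasive analysis of high-gamma (HG, 70–100 Hz)
cortical activity from multichannel EEG during cued motor imagery, together
with a spatial co-localization statistic against per-vertex fMRI Z maps.
This note documents the model, the statistical machinery, the synthetic
world used for validation, and the numerical choices.

## Signal model and source mapping

Trials are cue-locked 5 s segments, time axis −2 to 3 s, sampled at 1200 Hz.
The forward model is a leadfield **L** (channels × sources) on a triangulated
cortical surface, one fixed dipole orientation (the vertex normal) per
source, so a single weight row per source suffices (a *scalar* beamformer).

The LCMV (linearly constrained minimum-variance) spatial filter for source
*v* is

    w_v = C_r⁻¹ l_v / (l_vᵀ C_r⁻¹ l_v),     C_r = C + λ·mean(diag C)·I,

where **C** is the sample covariance of the broadband signal pooled over all
retained trials and the full trial window, and λ = 0.05 by default.  The
rows stack into a transfer matrix **T** with the unit-gain property
`T L = I` on the diagonal (checked to 1e−6).  Whether the covariance should
come from baseline only or the whole trial is an open modelling choice; we
pool the whole trial (more samples, stationary null) and expose the window
as an option.

Time-frequency decomposition uses complex Morlet wavelets on a 1 Hz grid
from 70 to 100 Hz (n_cycles = 7 for HG mapping, 5 for beta).  Because both
operators are linear, channel-domain coefficients map to source space per
trial as `j_i(t, f) = T d_i(t, f)`.  The trial statistic is the summed
**amplitude** `a(t, f) = Σ_i |j_i(t, f)|` (amplitudes, not powers, to damp
outlier trials; the sum is kept literally without 1/N since the subsequent
normalization cancels any scale).  Per source and frequency, `a` is
converted to Z-scores against the mean and standard deviation (over time,
sample SD with n−1) of the −1 to 0 s baseline.

## Maximum-statistic permutation test

The null hypothesis is exchangeability of the baseline second (−1..0 s) and
the signal second (0..1 s).  Each of the `n_perm` (default 1000)
permutations swaps those two segments for a uniformly drawn half
(⌊N/2⌋ trials, without replacement) of the retained trials, rebuilds
`a` and its baseline Z-scores, and records the **maximum Z over the signal
window, the full 70–100 Hz grid, and all sources**.  Because the statistic
is already the joint maximum, its null histogram controls the family-wise
error over time × frequency × space with no further correction; an outlier
trial inflates the null maxima along with the observed one, so the test also
enforces trial-to-trial stability.  p-values use the add-one convention
`p = (1 + #{null ≥ observed})/(1 + n_perm)`, so p = 0 is impossible and ties
count against rejection.  The swap is applied to source-domain coefficient
magnitudes per frequency — algebraically identical to swapping the raw
segments before averaging, at a fraction of the cost.  Per-vertex p-values
(needed to define EEG clusters) compare each vertex's signal-window maximum
against the same global null histogram, so they remain family-wise.

EMG/EOG channels are monitored with the identical machinery applied to
their 70–100 Hz Hilbert envelopes, one channel at a time, to expose
systematic task-locked muscle or ocular contamination that the cortical
permutation test cannot see.

## Artifact-trial rejection

Contaminated trials are removed, never repaired.  Three configurable rules,
each reproducing a qualitative criterion with a declared quantitative
default:

- **hg_extreme** — a trial's channel-mean HG power exceeds, at any time,
  (1 + factor) × the pooled 99th percentile of HG power over time (factor
  1.0).  The percentile for trial *i* pools the *other* trials
  (leave-one-out): a grossly contaminated trial must not lift its own
  threshold out of reach.
- **hf_power** — mean 100–150 Hz power above k = 5 × the across-trial
  median (muscle spectra keep rising above 100 Hz; cortical EEG does not).
- **sync_multi** — ⌈n_channels/4⌉ or more channels exceed their own robust
  (median + 6·1.4826·MAD) envelope threshold within one 50 ms window.

Flags are monotone (a rule can only add flags) and permutation-equivariant.

## EEG–fMRI cluster proximity

Supra-threshold vertices (fMRI: Z > 2.3; EEG: permutation p ≤ 0.1) are
grouped into connected components under mesh edge adjacency.  Each cluster
is summarized by its centroid and mean spherical radius (mean member-to-
centroid Euclidean distance).  The distance between two clusters is the
centroid separation minus both radii, floored at zero on overlap.  Every
fMRI cluster is matched to its nearest EEG cluster; when fMRI clusters
outnumber EEG clusters only the #EEG smallest distances are kept; the
compound measure is the median of the kept distances (mm).  Plain 3-D
distances deliberately stand in for geodesics: the measure targets gross,
multi-centimeter mismatches.

Significance: the fMRI clusters are relocated `n_resamples` (default 1000)
times to random mesh positions, preserving the cluster count and each
cluster's exact vertex count by growing breadth-first patches with a
randomly ordered frontier (the simplest connected, shape-agnostic choice —
only count and size are pinned).  Placement does not exclude the original
location (exclusion would bias p upward), and clusters within one resample
stay disjoint.  `p = (1 + #{null compound ≤ observed})/(1 + n_resamples)`.

Group maps are plain vertex-wise means across subjects; the threshold on a
mean of n independent standard-normal maps equivalent to a single-map
threshold z is `z/√n` (2.3/√10 = 0.727 for ten subjects, matching the
published 0.72 at its printed precision), with one-sided confidence level
Φ(z) (Φ(2.3) ≈ 0.989, i.e. 99 %).

## Peak-frequency readout

Localization and spectral readout need different resolutions.  The mapping
wavelet (7 cycles ⇒ σ_f ≈ f/7 ≈ 11 Hz at 80 Hz) is deliberately broad — good
time resolution inside the 0.3–1.0 s response, good maps — but cannot place
a narrowband peak on a 1 Hz grid.  The pipeline therefore re-estimates the
band peak at the already-localized vertex only: the beamformed source
waveform is decomposed with an 80-cycle wavelet (σ_f ≈ 1 Hz), the profile is
the baseline-corrected amplitude gain per frequency (signal-window mean
minus baseline mean; dividing by the noisy baseline SD would only blur the
peak location), and the grid maximum is refined by parabolic interpolation.
In the recovery simulations this reads the simulated center back to a few
tenths of a Hz.

## Synthetic world

The generator emulates the study protocol as stated: 54 channels (1200 Hz),
100 trials per hand, cue at t = 0, HG bursts centered 70–96 Hz confined to
0.3–1.0 s post-cue at a contralateral source vertex, beta-band (default
21 Hz) rhythm attenuated post-cue (ERD depth 0.5), 1/f background noise
(α = 1) spatially mixed across channels, broadband 20–300 Hz muscle bursts
on random channel subsets in a configurable fraction of trials, and bipolar
EMG/EOG channels with optional task-locked contamination.

- Geometry is a jittered spherical cortex (radius 70 mm) triangulated on the
  unit sphere, inside a spherical full-shell sensor array (radius 100 mm);
  the leadfield is the analytic current-dipole potential in an infinite
  homogeneous conductor (σ = 0.33 S/m), oriented along vertex normals.
  This preserves the structure that matters at desk scale (focal,
  distance-attenuated, spatially mixed topographies) and real leadfields
  remain loadable.
- `hg_snr` is the ratio of burst amplitude to the noise's in-band RMS at the
  most sensitive channel.  The noise calibration is analytic (the 1/f band
  fraction), so the ratio has a fixed meaning independent of the
  realization.  Scalp HG SNR is not an empirically known number; the default
  2.0 marks the regime where recovery is expected to work.
- Bursts are Hann-windowed narrowband Gaussian noise (5 Hz FWHM), not pure
  tones — narrowband character without phase locking.
- Muscle artifacts are 10× channel-SD bursts, reflecting that scalp EMG
  exceeds cortical HG by orders of magnitude.
- All outputs are pure functions of (config, seed); per-trial noise comes
  from spawned substreams of one master `SeedSequence`.

What the generator does **not** emulate: realistic head geometry and
conductivity layers, inter-subject anatomical variability, electrode
digitization error, non-stationary noise floors, eye-movement artifacts with
realistic topographies, or fMRI physiology (vertex maps are Gaussian blobs
plus distractors).  A green recovery test therefore establishes that the
*algorithmic chain* is correct and calibrated on data with the stated
structure — not that scalp HG is recoverable from any particular real
recording.

## Numerical choices

- Morlet kernels are L1-normalized Gaussians (support ±5σ_t); a unit cosine
  at the analyzing frequency yields |coefficient| ≈ 0.5, matching the
  closed-form transfer function used as the test oracle.  Samples within one
  kernel half-width of a trial edge are masked invalid, never zeroed; the
  baseline window must be fully valid.
- Decimation (default factor 10 in the pipeline ⇒ 120 Hz coefficient rate)
  is exact: the inverse FFT is taken on the alias-folded spectrum, verified
  against naive slicing to 1e−10.
- The session pipeline runs the mapping and permutation stages in single
  precision (Z-scores are O(1)–O(100); float32 is ample) and crops trials,
  kernel-width-aware, to a margin around the analysis windows.
- Zero baseline SD marks a location invalid (NaN Z, reported) rather than
  raising; the max statistic skips invalid cells and breaks ties toward the
  lowest (vertex, frequency, time) index.
- Butterworth band-passes are designed by `buttord` for ≥ 40 dB stop-band
  (50/120 Hz for the HG band) and applied forward-backward (zero phase), so
  envelope timing is unbiased relative to the cue.

## Known limitations

- The beamformer assumes fixed normal orientations; a max-power orientation
  option is not implemented.
- Cluster extraction treats the mesh graph as given; extremely anisotropic
  triangulations would distort both adjacency and the BFS resampling shapes.
- The permutation test is one-sided (HG increases); beta-band decreases are
  mapped but not tested for significance.
- With fewer than ~10 trials the permutation null is coarse
  (≥ 19 permutations are enforced; p resolution is 1/(n_perm+1)).
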