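# Methods

This note documents the models, estimators and design choices behind
`alphafield`, and what the synthetic cohorts do and do not establish about
real data.

## Spectral readouts

**Power spectra.** Runs are split into consecutive non-overlapping 10-s
epochs aligned to the run start; an epoch overlapping any marked artifact
segment is dropped whole. Each epoch is mean-detrended and tapered with
DPSS windows (time–half-bandwidth product NW = epoch length × smoothing
half-width; 2NW−1 tapers, i.e. 9 tapers at the default 10 s / 0.5 Hz), and
tapered periodograms are averaged over tapers, epochs and channels (Oz,
POz by default). The output grid is 0.1 Hz via zero padding; a coarser
grid than 1/epoch-length is rejected rather than silently truncating
epochs. Eyes-closed-style estimation at 0.2 Hz is available through the
`epoch_length`/`resolution` parameters.

**IAF detection.** The IAF is the highest spectral peak in 8–12 Hz. The
published analyses made this call visually; the reproducible surrogate
used here requires the in-band maximum to be a local maximum of the
spectrum with prominence at least 20% of the median in-band power
(configurable). A flat or peak-free band returns a non-identifiable flag;
a subject with no identifiable run is excluded, which is how the enrolled
cohort shrinks (22 → 18 in the emulated design). Accuracy: on pure tones
the detected peak is within the 0.1 Hz grid everywhere in 8–12 Hz
(tested); on noisy amplitude-modulated runs the dpss smoothing makes the
peak top nearly flat, and the argmax is accurate to roughly a quarter of
the smoothing bandwidth (empirically ≤ 0.15 Hz) — an estimator property
worth knowing when interpreting MISMATCH values of that order.

**Alpha amplitude.** Band-pass ±2 Hz around the IAF with a zero-phase
forward–backward 4th-order Butterworth (effective order 8). The source
description of the filter ("Butterworth with Hamming window") is
internally contradictory; the zero-phase Butterworth without a window is
the standard reading and is what the envelope oracle tests pin down. Each
contiguous artifact-free segment is filtered and Hilbert-transformed
independently — an artifact can therefore never ring into the average
regardless of its amplitude — and 1 s is trimmed from each segment end to
suppress the remaining edge transients (transient decay for this filter is
≪ 1 s). The envelope is averaged over kept samples per channel, then over
channels; with a shared artifact mask the averaging orders coincide
(asserted in tests). Whether per-run IAFs entering MISMATCH should be
duration-weighted is left open upstream; they are unweighted here.

## EEG-informed fMRI fusion

**HRF.** Canonical double-gamma: response gamma with mode 6 s, undershoot
gamma with mode 16 s (both rate 1/s), undershoot ratio 1/6, 32-s support,
kernel normalized to peak 1 and sampled on the EEG grid.

**Alpha regressor.** Per channel: band-limited Hilbert envelope of the
whole run → convolution with the HRF → averaging within each
[i·TR, (i+1)·TR) window (integration doubles as anti-aliasing and is
oracle-testable) → channel average. The first ⌈32 s / TR⌉ volumes carry
convolution warm-up; they are retained in the GLM (no trimming is
specified upstream) but `warmup_volumes` exposes the count for
sensitivity checks.

**Voxelwise GLM.** Ordinary least squares of each voxel's series on the
regressor, an intercept, and polynomial drift terms up to `drift_order`
(default 1) on a [−1, 1] time axis; t = estimate / standard error with
dof = T − (drift_order + 2). Exactly constant voxels get t = 0 (guarded
0/0); exactly coupled noiseless voxels keep the huge finite t implied by
the float64 residual floor. Negative alpha–BOLD coupling gives negative t.
The per-subject map is the voxelwise mean of the four pre/post run maps,
which assumes a session- and run-stable coupling topography.

**Dose masks.** MASK_alphaBOLD = the k most-negative pooled-t voxels
within occipital∩gray (k = 1000 by default; the 10,000-voxel variant is a
parameter change); MASK_strong = the k largest-field voxels within gray.
Ties break by ascending linear voxel index, making selection deterministic
across platforms. Masks, maps and fields must share grid and affine
byte-exactly or the operation errors. EFIELD values are arithmetic means
of the field magnitude over the mask. Because MASK_strong maximizes the
mean over all equal-size gray subsets, EFIELD_strong ≥ EFIELD_alphaBOLD
for every subject; this ordering is asserted per synthetic subject.

## Connectivity

mPFC (1, 55, −3) and PCC (1, −61, 38) sphere ROIs of 10 mm radius
(voxel-center distance ≤ radius, boundary inclusive); synthetic cohorts
carry translation-scaled ROI specs because the MNI coordinates lie outside
the desk-scale grid. Connectivity is the Spearman correlation (average
ranks for ties) of the two ROI mean time courses, Fisher-z transformed
after clamping |ρ| ≤ 1 − 1e−7 so perfectly monotone series stay finite
with the right sign. No band-pass is applied here: denoising/filtering is
a preprocessing concern, so users of real data should filter upstream.

## Statistics

All model fits are OLS with intercept (statsmodels behind the module
surface; each estimate is pinned to a normal-equations oracle in tests).
RMSE uses divisor n (configurable), which makes the in-sample RMSE
directly comparable to the LOOCV RMSE; LOOCV is computed exactly through
the hat-matrix identity e₍loo₎ = e/(1−h) and equals the explicit n-refit
brute force. The 2×2 repeated-measures ANOVA uses per-effect
subject-interaction error terms with dof (1, n−1) — the published table
prints F(1,16) with n = 18, which the implementation does not imitate; dof
follow the data. The ANCOVA on post−pre changes tests the session term of
`delta ~ session + ΔSLEEPINESS` on the stacked 2n rows, dof (1, 2n−3).
`residualize_then_correlate` regresses the covariate out of the response
only (a both-sides variant is available by flag). Bonferroni correction
defaults to the four-model family, threshold 0.05/4 = 0.0125. Whether to
drop MISMATCH is a user decision: all four variants plus the reduced model
are always fitted.

## Synthetic cohorts

The generator's defaults are the study conditions of the emulated design:
18 subjects, two sessions × three 7-min runs, 250 Hz EEG (the acquisition
rate is irrelevant below a 160 Hz analysis band), TR 2 s with 210 volumes,
a 24³ grid of 3-mm voxels.

*EEG*: an amplitude-modulated sinusoid at the subject's IAF (drawn from
9–11 Hz; between-run drift is a bounded random walk with 0.15 Hz steps)
over 1/f background noise (1 µV SD). The stimulation frequency is the
base IAF rounded to the 0.2 Hz grid of an eyes-closed FFT, so MISMATCH is
nonzero and realistic (median ≈ 0.3 Hz). The envelope modulator is
band-limited to 0.01–0.08 Hz, re-centred on the window surviving the 1-s
readout trim so planted run amplitudes read back exactly. The stimulation
run carries a 200 µV artifact at the stimulation frequency and a
whole-run artifact segment, and is flagged unusable.

*Amplitudes*: per subject, baseline ≈ 4 µV with a shared pre→post drift in
both sessions; the tACS-post amplitude adds the planted contrast
ΔΔ = −1.5 + 0.9·ΔΔ SLEEPINESS + 11.7·EFIELD_alphaBOLD + N(0, 0.3 µV).
Sleepiness run values are drawn in [0, 1] (clipped after drawing; the
realized post-clip contrast is what enters the planted equation, keeping
the ground-truth invariant exact). No distributional form for sleepiness
changes is asserted upstream, only spreads; the ΔΔ SD (0.45) is the
root-sum-of-squares of the two reported session SDs (0.34, 0.31) and is a
parameter.

*BOLD*: every voxel is `coupling × (HRF-convolved, TR-binned envelope) +
white noise`, with the coupling weight two Gaussian blobs (σ = 0.1·FOV) in
medial-occipital cortex — the calcarine-like location of alpha generators
— and the planted coupled set defined as the top-k weights within
occipital gray. The BOLD noise SD (180 in regressor units) places the
per-run |t| at the planted-mask boundary near 40: strong enough that the
t-ranking tracks the coupling weight (boundary recovery with Jaccard
≈ 0.97 at defaults, ≥ 0.95 asserted), weak enough that null calibration
is untouched. In the exactly-zero-BOLD-noise limit the t-ranking among
perfectly fit voxels degenerates to float-epsilon residuals, so the
"noiseless" verification cohorts switch off the response and EEG noise
while keeping BOLD noise at its default. DMN-like signals (5× voxel noise)
with a planted per-run correlation are added inside the two ROI spheres.

*Field maps*: two Gaussian sources at posterior-lateral scalp positions
(PO7/PO8 surrogates, width 0.25·FOV) with small per-subject jitter of
centers and widths (anatomy surrogate), normalized per subject so the mean
over the planted mask is exactly 1, then scaled by a log-normal
subject factor with mean 0.12 V/m and 25% CV — the published dose
descriptives. A deliberately accepted limitation: with a field this smooth
the realized EFIELD_strong exceeds EFIELD_alphaBOLD by only ~10%, not the
~2.2× of finite-element fields. A steeper parametric field reproduces the
contrast but makes mask-boundary swaps dose-biased at desk scale,
violating the noiseless ground-truth consistency that the verification
suite depends on; the ordering and the alphaBOLD-variant superiority are
preserved either way. The feature-level generator (below) draws
EFIELD_strong from the printed 0.27 ± 0.07 directly.

`simulate_feature_table` is the tabular counterpart used for statistical
calibration and coefficient-recovery studies: predictors from the
population descriptives, response from the planted model, MISMATCH
half-normal with scale 0.45 Hz (median 0.30 Hz), and a connectivity
response driven by sleepiness alone (slope 0.4, residual SD 0.25, giving
R² ≈ 1/3 for the connectivity model, the scale of the published fit).

**What passing tests show — and don't.** The synthetic data are
artifact-free (the artifact mask machinery is honored but gradient or
ballistocardiogram residuals are never synthesized), the coupling
topography is stationary, BOLD noise is white, and the EEG background has
no non-alpha rhythms. Passing therefore establishes the correctness of the
estimators and the recoverability of planted effects under the stated
conditions, not robustness to real preprocessing failures, head motion, or
physiological confounds.

## Problem sizes used in verification

Unit tests run on reduced cohorts (16³ or 12³ grids, 1–2 min runs,
masks of ~60–150 voxels scaled to the smaller occipital label). The
acceptance suite runs the zero-noise end-to-end check on the default 24³
grid with 6 subjects, the mask-recovery check on default-noise subjects at
full scale, coefficient recovery on 200 tabular 18-subject cohorts, and
null calibration on 500 cohorts plus 10⁴ null voxels. These sizes are the
package's verification conditions; all scale upward by configuration.

## Known limitations

- The electric-field stand-in is parametric; no finite-element head
  modelling, hence the dose-contrast limitation above.
- `generate_cohort` holds the full cohort in memory (~1.5 GB at default
  scale, float32 BOLD); `iter_cohort` streams subjects for larger runs.
- EDF files are read (via MNE) but not written; the documented TSV is the
  interchange format for EEG.
- The pipeline analyses the supplied volumes as-is: motion correction,
  normalization, smoothing and nuisance regression are out of scope.
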