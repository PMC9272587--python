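# alphafield

Analysis pipeline for **aftereffects of alpha-band transcranial alternating
current stimulation (tACS)** measured with simultaneous EEG–fMRI, together
with a synthetic cohort generator that makes every stage verifiable against
planted ground truth.

## The scientific problem

tACS aftereffects on the EEG alpha rhythm are notoriously variable between
subjects, and plain group statistics often miss them. The approach
implemented here explains that variability with subject-specific factors:
the electric-field dose that actually reaches alpha-generating cortex, the
mismatch between the stimulation frequency and the individual alpha
frequency (IAF), and concurrent changes in sleepiness. For each subject
(two sessions — tACS and sham — of three runs *pre*, *stimulation*,
*post*) the pipeline derives:

- **ΔΔ ALPHA_AMP** (µV) — the alpha amplitude is the time-mean Hilbert
  envelope of the Oz/POz EEG band-passed ±2 Hz around the IAF (zero-phase
  4th-order Butterworth); the readout is the session contrast of post−pre
  changes, (post−pre)\_tACS − (post−pre)\_sham.
- **MISMATCH** (Hz) — |f\_tACS − mean IAF of the tACS session|, with the IAF
  as the highest identifiable 8–12 Hz peak of a 10-s-epoch multitaper
  spectrum (0.1 Hz grid, 0.5 Hz smoothing); subjects without an
  identifiable peak are excluded.
- **EFIELD_alphaBOLD / EFIELD_strong** (V/m) — the simulated field
  magnitude averaged over two subject-specific 1000-voxel gray-matter
  masks: the most negatively alpha-coupled occipital voxels (from a
  voxelwise GLM of BOLD on the HRF-convolved alpha envelope, t-maps pooled
  over the four pre/post runs) and the highest-field voxels.
- **ΔΔ CONNECTIVITY** (z) — Fisher-z Spearman correlation of the mPFC and
  PCC 10-mm sphere-ROI time courses, contrasted as above.
- **ΔΔ SLEEPINESS** — the same contrast of visual-analogue sleepiness
  ratings in [0, 1].

The inferential battery is the 2×2 within-subject ANOVA, an ANCOVA with the
sleepiness covariate, and the multiple linear regression

    ΔΔ ALPHA_AMP ~ β₁·ΔΔ SLEEPINESS + β₂·EFIELD + β₃·MISMATCH + β₄

fitted in four variants (two responses × two dose definitions) with
Bonferroni correction (p < 0.05/4 = 0.0125) and leave-one-out
cross-validation; dropping the uninformative MISMATCH term yields the
reduced model whose planted form in the synthetic cohorts is

    ΔΔ ALPHA_AMP = 0.9·ΔΔ SLEEPINESS + 11.7·EFIELD_alphaBOLD − 1.5 + ε.

## Worked example

Generate a small synthetic cohort, run the full pipeline, and print the
model table (reduced grid and mask size for speed; defaults are a 24³ grid
of 3-mm voxels with 1000-voxel masks):

```bash
$ alphafield simulate --out demo/cohort --subjects 8 --seed 4 --grid 16
grid 16^3: planted mask reduced to 154 voxels
wrote 8-subject cohort to demo/cohort

$ alphafield features --cohort demo/cohort --out demo/out --k 150
8 subjects included, 0 excluded; outputs in demo/out

$ alphafield report --features demo/out/features.csv
n = 8 subjects; Bonferroni threshold p < 0.0125
model                model p     R2   RMSE  LOOCV  sig
alpha_alphabold       0.0267   0.88   0.15   0.30
alpha_strong          0.0658   0.81   0.19   0.35
conn_alphabold        0.3602   0.52   0.17   0.32
conn_strong           0.4443   0.45   0.18   0.30
reduced model: dd_alpha_amp = 0.71 x dd_sleepiness + 6.43 x efield_alphabold -0.70   (R2 = 0.78)
```

Reading the output: the amplitude model using the alpha-coupled dose
(`alpha_alphabold`) explains the most variance — the planted structure of
the synthetic cohort — while the connectivity models are weaker; RMSE is
the in-sample root mean squared residual (µV) and LOOCV its held-out
counterpart. At n = 8 the reduced-model coefficients are noisy single-cohort
estimates of the planted (0.9, 11.7, −1.5); averaged over many cohorts they
recover them (see below). `demo/out/features.csv` holds the six features
per subject with units in the headers, and `report.json` the full model,
ANOVA and ANCOVA results.

The same steps are available as library calls (`alphafield.generate_cohort`,
`alphafield.run_pipeline`, `alphafield.fit_model_variants`); a single
subject's pooled t-map and dose masks can be written with
`alphafield fuse --subject demo/cohort/sub-01 --k 150 --out maps/`.

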