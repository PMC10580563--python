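# neuropda

A desk-scale, fully synthetic implementation of the computational pipeline
behind mindfulness-based real-time fMRI neurofeedback (mbNF) targeting the
default mode network (DMN) in adolescents: personalized network
localization, a closed-loop feedback engine, and the pre-registered
connectivity and power analyses.  Everything runs on a generated BOLD
phantom — no scanner, no subject data — so every stage of the protocol is
exercisable and testable end to end.

## What it implements

- **`bold_sim`** — a voxel phantom (24³ grid, 2 mm voxels) partitioned into
  DMN hubs (mPFC, PCC), DMN core, FPN, WM, CSF and other tissue; BOLD runs
  built from AR(1) network latents with controllable DMN–FPN
  anticorrelation and mPFC–PCC coupling, linear drift, Gaussian noise, and
  rigid-motion traces with spikes; streaming access that emulates
  real-time volume export.
- **`localizer`** — brain extraction, 5 mm FWHM smoothing, 0.01 Hz
  high-pass; trimming and temporal concatenation of two resting runs
  (second run dropped below 125 volumes); 35-component spatial ICA;
  selection of the component with the highest |spatial correlation| to
  each network template; masks binarized to the 2000 strongest
  template-supported voxels, with a template-fallback path.
- **`rtengine`** — one incremental GLM per mask voxel, updated each volume
  with Gentleman's square-root-free Givens algorithm (intercept, six
  relative-displacement motion regressors, linear drift).  Residuals are
  z-scored against the first-25-volume (30 s) baseline; network activation
  is the inverse-baseline-variance weighted mean of voxel z-scores; the
  feedback quantity is the Positive Diametric Activity,
  `PDA = z_FPN − z_DMN`, with volumes flagged outliers when either |z| > 2.
- **`feedback`** — ball velocity = gain × PDA; hits flash, reset the ball
  and shrink the hit circle by 10%; between runs the gain recalibrates
  ×1.25 (< 3 hits), ×0.75 (> 5 hits), else unchanged; full 15-min and
  30-min dose schedules; whole-visit simulation.
- **`postconn`** — nuisance cleaning (12 motion regressors, 5+5 aCompCor
  components, drift, optional GSR), 0.008–0.09 Hz bandpass, FD censoring;
  mPFC–PCC Pearson correlation with Fisher r-to-z; the pre-registered
  mixed models `fisher_z ~ time + mean_fd + age + (time | id)` and the
  dose × time variant, with AIC random-structure selection, a Huber-IRLS
  robust path, Benjamini–Hochberg multiplicity control, MNAR shift
  sensitivity, and item-level imputation.
- **`powercalc`** — repeated-measures ANOVA power via the noncentral F
  distribution, `λ = f²·N·m/(1−ρ)·ε`.
- **`randomize`** — stratified permuted-block assignment to the two dose
  arms.

## Worked example

```bash
python examples/localize_networks.py
```

```
provenance: personalized
DMN: component  7 (|spatial r| = 0.79), 2000 voxels, Jaccard vs ground truth 0.77
FPN: component  0 (|spatial r| = 0.87), 2000 voxels, Jaccard vs ground truth 0.77
```

Two simulated resting runs (250 + 240 volumes, trimmed and concatenated to
480) are decomposed into 35 spatial components; the components most
correlated with the DMN and FPN templates are thresholded to exactly 2000
voxels each, and both masks recover the planted networks' cores (Jaccard
0.77 against ground truth, whose ceiling here is 2000/2600 ≈ 0.77).

`examples/` holds one short script per capability — phantom simulation,
localization, streaming feedback, a full dosing session, the cohort
connectivity analysis, and the power calculation.  A thin CLI mirrors
them: `neuropda simulate|localize|session|connectivity|analyze|power|randomize|pipeline`.

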