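# Methods

This note documents the models, numerical choices, and limitations behind
the package.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The synthetic BOLD phantom

The phantom stands in for a participant's head: brain voxels fill a
superellipsoid inside a 24×24×24 grid of 2 mm voxels, partitioned into
disjoint regions — mPFC (200 voxels), PCC (200), DMN core (2200), FPN
(2600), WM (800), CSF (400), other tissue (600).  Regions grow from
seed-jittered anchors, claiming their nearest unassigned voxels, so
counts are exact and placements vary by seed.  DMN and FPN templates
(2600 voxels each) exceed the 2000-voxel mask threshold by design, and
the hub ROIs sit at the 200-voxel minimum below which the connectivity
stage substitutes templates.

Signals are region-level latents: stationary unit-variance AR(1)
processes (default φ = 0.3 per 1.2 s volume) whose innovations carry a
target correlation matrix — every DMN latent correlates `network_corr`
with the FPN latent (default −0.3, the anticorrelation the feedback aims
to strengthen) and `mpfc_pcc_corr` with its DMN siblings (default 0.7,
the within-DMN coupling the outcome analyses track).  The matrix is
checked for positive semi-definiteness at construction.  Voxel series are
latent × amplitude × a Gaussian loading profile tapering from the region
core (mean 1, so amplitudes keep their stated scale), plus a nominal
100-unit mean, linear drift, i.i.d. Gaussian noise, and optionally an
additive term proportional to relative head displacement.  No HRF
convolution is applied: the feedback loop operates on measured resting
signal, not stimulus-locked responses, and the analyses only assume the
correlational structure.

Motion traces are slow random walks (0.02 mm / 0.0004 rad per-volume
steps) with translation spikes at designated outlier volumes.  Framewise
displacement is the sum of absolute relative displacements with rotations
converted on a 50 mm sphere — the standard head-radius convention; the
exact rigid-body matrix formulation is not needed at this scale.  Motion
never resamples the image, which makes the real-time engine's
nuisance-regression premise exactly true in the phantom; consequently the
simulations cannot probe interpolation artifacts or spin-history effects.

What passing tests show, therefore, is that every computational mechanism
behaves as specified under the statistical structure real data are
assumed to have — not that the pipeline is robust to EPI physics,
susceptibility distortion, physiological noise, or registration error,
all of which are out of scope.

## Localizer

Preprocessing: brain extraction by robust intensity threshold (2nd–98th
percentile range), Gaussian smoothing with FWHM specified in mm,
temporal high-pass as a zero-phase order-2 Butterworth at 0.01 Hz
followed by exact demeaning.  Realignment is the identity in synthetic
space.  Run concatenation trims both runs to the shorter length, aligns
the second run to the first by intensity-centroid translation (the two
share one coordinate frame by construction, so full affine registration
is unnecessary), demeans each run voxelwise, and joins them in time; a
second run under 125 volumes is dropped, and a first run under 125
volumes aborts to the template-fallback path.

Spatial ICA treats voxels as samples and timepoints as features, so
sources are spatial maps and the mixing matrix holds timecourses.  The
interface always returns 35 components.  Internally, PCA reduces to 35
dimensions and the fixed-point (FastICA, logcosh) rotation runs only on
the estimated signal subspace — eigenvalues exceeding twice the median of
the leading 35 — with the remaining principal-component maps returned
unrotated.  Running the fixed-point iteration on all 35 dimensions when
the data hold far fewer genuine sources over-learns: it shatters large
network maps into sparse fragments (a flat blob covering ~25% of the
brain is spatially sub-Gaussian, and splitting it raises the contrast
function), which probabilistic-ICA tools avoid through their internal
dimensionality handling.  Non-convergence retries twice with
deterministic sub-seeds, then accepts the final unmixing: the library's
convergence flag is far stricter than component selection requires.

Component selection maximizes |Pearson correlation| between map and
binary template; a negative winning correlation flips the map's sign so
"strongest positive weights" is well defined.  If one component wins both
networks it keeps the network with the larger |correlation| and the other
network takes its runner-up (logged).  Mask personalization keeps the
`n_vox` = 2000 largest positive weights inside the template support, ties
broken by ascending linear voxel index for determinism; fewer than 2000
positive support voxels keeps them all and records a warning.  Map
z-scoring before thresholding is immaterial to mask content (ranking is
invariant to monotone scaling), so maps are simply variance-normalized.

## Real-time engine

Each volume appends one row to a per-voxel least-squares system with 8
regressors: intercept, six relative-displacement motion terms (zero at
volume 1), and a linear drift term scaled to [−0.5, 0.5] over the
expected run length (scaling is for conditioning only; with the intercept
present, residuals are invariant to affine rescaling).  The intercept is
a deliberate addition — without it, baseline z-scoring would conflate
mean signal with activation.  Updating uses Gentleman's square-root-free
Givens rotations; because all voxels share the design row, one triangular
factor is shared and only the projected responses are per voxel, so an
update is O(p²) scalar work plus O(p) vector operations over mask voxels
(≈0.3 ms per volume on the default grid, against a 1.2 s TR).
Structurally zero columns (e.g. a motionless axis) have zero scale in the
factor and drop out of the back-substitution with zero coefficients;
tests verify agreement with batch least squares to 10⁻⁸ at every
timepoint.

At volume 25 the baseline freezes: residuals of volumes 1–25 under the
t = 25 coefficients give per-voxel means and sample SDs (n−1), read as one
coherent baseline sample rather than a sequence of evolving fits.
Efficiency weights are 1/SD² normalized to sum 1 within each mask.
Voxels with baseline residual SD ≤ 10⁻⁸ (nuisance-spanned signal) are
excluded from weighting and contribute z = 0; a fully degenerate mask
reports activation 0 rather than failing, and all exclusions are logged.
Masks are intersected with the whole-brain mask eroded by one voxel
(6-connectivity) before use.  Non-finite volumes are rejected without
updating the fit and, post-baseline, emit an outlier-flagged sample.

## Feedback controller

The ball moves gain × PDA per volume on a vertical track between two
circles; hits reset it to center, flash the circle for exactly one volume
(during which no movement integrates), and shrink that circle's radius by
10%.  The protocol's 2-D geometry leaves open how a shrinking radius
interacts with a "reaches the center" criterion, so both readings are
implemented behind `radius_mode`: the default `boundary` maps radius r to
a hit boundary at |y| = 2 − r, so each shrink pushes the target 0.1
screen units farther and the rule is consequential as adaptive
difficulty; `cosmetic` keeps the boundary at ±1 and treats the radius as
display-only.  In boundary mode the position range extends with the
boundary (|y| < 2); in cosmetic mode it is [−1, 1].  Outlier volumes
pause the ball in place.  Between feedback runs the gain multiplies by
1.25 / 1.0 / 0.75 for < 3 / 3–5 / > 5 hits; the initial gain default 0.05
(screen units per PDA-SD per volume) is an artifact choice sized so a
sustained |PDA| = 1 crosses to a circle in ~20 volumes.  Radii reset at
each run start by default (per-run difficulty), gain persists across
runs; both are configurable, as the protocol does not specify.  The
session simulator runs the full visit: localizer rest runs → masks →
scheduled no-feedback/feedback/rest runs with a fresh engine and baseline
per run, logging PDA, ball position, pauses, hits, gains and radii.

A consequence of the all-volumes incremental nuisance model worth noting:
a sustained activation offset is progressively absorbed by the intercept,
so only transient fluctuations keep driving the ball.  The session
scenario's `fpn_shift` therefore produces an early post-baseline response
that decays — visible in `examples/realtime_feedback.py` — and hit counts
are dominated by moment-to-moment variability, which the between-run gain
calibration then regulates.

## Connectivity analyses

Cleaning builds one nuisance design per run — intercept, 6 motion
parameters and their first differences, top-5 PCA timecourses of WM and
of CSF voxels (aCompCor), linear drift, and optionally the mean
gray-matter signal (GSR; gray = brain minus WM/CSF) — projects it out
voxelwise, then bandpasses residuals with a zero-phase order-4
Butterworth at 0.008–0.09 Hz.  Volumes with FD above 0.3 mm (an
artifact-chosen default; the protocol defers the threshold to analysis
time) are flagged and excluded at the correlation stage
(filter-then-censor).  Connectivity is the Pearson correlation of mean
mPFC and PCC timecourses over retained volumes, clipped to ±(1−10⁻⁷)
before atanh so the Fisher z is always finite; a personalized ROI under
200 voxels is replaced by its template and flagged.

The Aim-1 model is `fisher_z ~ time + mean_fd + age_c` with per-participant
random effects; Aim 2 adds `dose*time` with the interaction as the focal
term (plus a sensitivity variant without the dose main effect).  Time and
dose are 0/1 indicators, age is centered, mean FD is the per-run motion
covariate.  Random-intercept and random-slope structures are compared by
AIC on maximum-likelihood fits — REML likelihoods are not comparable
across random-effects structures — and the winner is refit by REML;
fits fall back from L-BFGS to BFGS on numerical failure, and degenerate
data fall through to a flagged OLS path rather than crashing.  If any
outcome lies ≥ 3 SD from the outcome mean, estimation switches to a
Huber-weighted IRLS: statsmodels' mixed model accepts no observation
weights, so each pass rescales the outcome and fixed-effect design rows
by √weight and refits — an approximation that bounds the influence of
gross outliers on the fixed effects but does not reweight the
random-effects likelihood exactly, and that squares the weight on
product-interaction columns.  Weights derive from marginal
(fixed-effects) residuals, since BLUP prediction can fail on singular
random-effect covariances.

Benjamini–Hochberg step-up is applied within the pre-specified outcome
families (sizes 4 and 3); the implementation is checked in tests against
both a brute-force step-up oracle and statsmodels.  The MNAR sensitivity
refits the model with missing outcomes replaced by the observed mean plus
shifts across −2…+2 SD (9-point grid by default); with no missingness it
returns a single identity row.  Scale scores use person-mean item
imputation below 10% missing items, otherwise score missing.

## Power

For a within factor with m occasions, correlation ρ between repeated
measures and nonsphericity ε, the noncentrality is λ = f²·N·m/(1−ρ)·ε
with df₁ = (m−1)ε (×(g−1) for group-by-time interactions) and
df₂ = (N−g)(m−1)ε; power is the noncentral-F survival probability at the
central critical value.  `required_n` searches by doubling then bisection
and rounds grouped designs up to a multiple of the group count.  The
measurement count m is always an explicit argument.  A Monte-Carlo
cross-check in the tests exploits that at m = 2 the design collapses to a
paired t test with dz = f·√(2/(1−ρ)).  For the protocol's primary design
(f = 0.19, α = 0.05, ρ = 0.3, m = 2) this convention crosses 80% power at
N = 79 (power 0.7998 at 78); the complementary sensitivity view — the
minimal detectable effect at a fixed N — is exposed in
`examples/power_analysis.py`, and the acceptance audit file records λ,
degrees of freedom, and achieved power so the convention is checkable.

## Randomization

Permuted blocks (default size 2) within each of the 16 strata defined by
site, sex assigned at birth, prior mindfulness experience, and current
treatment, from a seeded generator; within a stratum, arm counts never
differ by more than half a block.

## Problem sizes and determinism

All randomness flows through explicit integer seeds; identical inputs
reproduce runs bit for bit.  Default problem sizes — 24³ grid, 250-volume
rest runs, 150-volume feedback runs, cohorts of tens of participants, and
replicate counts of 40–200 for recovery, type-I and FDR simulations — are
chosen so the full suite exercises every mechanism at statistically
informative scale on a single CPU; they are package defaults, and every
simulation accepts larger values.
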