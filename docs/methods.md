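# Methods

This note documents the models, parameter choices and numerical decisions
behind `vergefmri`, and what the synthetic generator does and does not
emulate.

## Study design being modelled

Two groups: binocularly normal controls (BNC, n = 7) and convergence
insufficiency patients (CI, n = 4) measured before and after 18 h of
vergence training (two 10-minute home sessions, three days a week, plus two
1-hour laboratory sessions a week, for six weeks). Primary measurements are
the peak velocity of 4° symmetric convergence step responses and the BOLD
percent signal change (PSC) in FEF, PPC and cerebellar vermis during an
alternating fixation / vergence-movement block design (20 s phases, 3.5
cycles, 140 s, TR 2 s, three repeated runs per subject). Broca's region is
carried through the identical pipeline as a non-stimulated control.

## Eye-movement analysis

* **Sign convention.** Monocular positions are stored rightward-positive and
  vergence is computed as left − right, so a symmetric convergence step
  (left eye rotating rightward, right eye leftward) is positive. A
  literal right-minus-left difference under the same axes would render
  convergence negative; positivity of convergence is the binding convention
  here and the difference is taken accordingly.
* **Calibration.** Each channel is a linear voltage→degrees map fit by least
  squares. Symmetric fixation at vergence angle θ places the left eye at
  +θ/2 and the right eye at −θ/2; each channel is regressed on its own
  per-eye target. The round trip degrees → volts (generator) → degrees
  (fit) is the identity on clean data.
* **Velocity.** Two-point central difference, v[i] = (x[i+1] − x[i−1])·fs/2;
  endpoint samples are undefined (NaN) and never participate in maxima. No
  smoothing is applied before differentiation (a config-gated low-pass
  exists but defaults off). Consequence: taking the maximum of a
  differentiated noisy trace biases peak-velocity estimates upward by an
  amount set by the position-noise level; the bias is common to all subjects
  and conditions, so group contrasts, monotonicity and correlations are
  preserved. At the generator's default monocular noise (0.01° RMS,
  roughly the 12-bit quantization scale of a ±25° acquisition range) the
  offset is ~2–3°/s.
* **Blink rejection.** Limbus trackers lose the signal during lid closure;
  any sample in either eye at or beyond the device's 25° linear range flags
  the whole trial (blinks at *any* point reject the response).
* **Saccade screening.** Saccade velocities are an order of magnitude above
  vergence velocities. A sample is saccadic when either monocular velocity
  exceeds max(5 × the running vergence-velocity scale, 40°/s); the floor
  keeps the threshold meaningful where vergence velocity is near zero. A
  trial is rejected only when a saccadic interval overlaps ±100 ms around
  the vergence velocity maximum; saccades elsewhere leave the peak
  measurable. The original analysis did this screening by manual phase-plot
  inspection; the automated criterion is this package's operationalization
  and has no numeric counterpart to match.
* **Peak search window.** Stimulus onset to onset + 2 s (slow CI responses
  can take ~2 s to fuse); ties resolve to the earliest sample.

## BOLD pipeline

* **Design regressor.** The fixation/movement boxcar is convolved with a
  canonical double-gamma HRF (response peak 6 s, undershoot 16 s, ratio 1/6,
  unit-sum normalized; cross-checked against nilearn's SPM HRF in the test
  suite) on a 0.1 s grid and sampled at volume midpoints.
* **Volume trimming.** The first 5 volumes are removed from data, motion and
  regressor alike.
* **Nuisance model.** 6 rigid-body motion parameters plus the top 5
  principal components of ≥99%-probability CSF voxels and of
  ≥97%-probability WM voxels (CompCor); PCs are zero-mean, unit-norm
  temporal singular vectors. Removal is by per-voxel OLS with the voxel
  mean re-added.
* **Design protection.** Confounds are estimated *jointly* with the task
  regressor and only the confound contribution is removed. Rationale: over
  a 65-volume run, 16 smooth regressors absorb a large fraction of the task
  variance by chance if removed sequentially (measured here at up to ~60%),
  biasing PSC toward zero; joint estimation is the standard task-fMRI
  treatment of confounds and leaves task amplitude unbiased. The pure
  sequential form remains available (`nuisance_regress` without `protect`)
  and satisfies exact residual orthogonality to all 17 design columns.
* **Band-pass.** FFT-domain mask passing 0.01–0.15 Hz with Gaussian
  roll-offs whose FWHM is 20% of each cutoff; DC always removed; voxel
  means kept separately and re-added for percent-change computation. The
  block fundamental (0.025 Hz) and its passband harmonics survive; the
  residual ~2% contrast attenuation is the main source of the small
  downward PSC recovery bias.
* **Thresholding and pooling.** Voxels inside each ROI mask with Pearson
  r ≥ 0.4 against the design regressor are averaged volume-wise. Task ROIs
  fall back to the full-mask mean (flagged) when no voxel survives; control
  ROIs always use the full-mask mean, since their purpose is the
  variability of a non-stimulated region. The 0.4 threshold is applied as a
  fixed constant with no degrees-of-freedom or autocorrelation correction —
  a fidelity choice, noted as a limitation.
* **Percent signal change.** Phase-labelled means — 100 × (movement mean −
  fixation mean)/fixation mean — with labels shifted by a 4 s hemodynamic
  delay (2 volumes) before assignment; unshifted labelling dilutes the
  contrast with transition volumes. A GLM-beta-scaled alternative was
  considered and not adopted; the phase-mean definition matches the
  task-vs-baseline comparison being modelled. Repeated runs are averaged at
  the PSC level, not the time-series level.

## Group statistics

Pooled-variance (equal-variance) unpaired t-tests, df = n₁+n₂−2; paired
t-tests on post−pre differences, df = n−1 (a zero-variance zero-mean
difference vector is reported as "no difference" rather than NaN). Two-sided
p-values; no multiple-comparison correction by default (config-gated),
matching the small-cohort design. The brain–behavior regression pools all
subject-condition rows (7 BNC + 4 CI-pre + 4 CI-post = 15 points), with
left/right PSC averaged per ROI pair and the midline cerebellar vermis
unaveraged. CISS totals are sums of 15 items scored 0–4; totals ≥ 21 are
symptomatic.

## Synthetic generator

The generator's defaults are the study conditions; they are fixed once and
documented here.

* **Vergence steps.** Logistic position profile parameterized by amplitude
  and peak velocity (max slope = 4·pv/A at the midpoint): monotone, twice
  differentiable, and qualitatively matching recorded convergence steps. A
  peak velocity whose 1–99% rise does not fit the trial duration is
  rejected as infeasible. Blinks are modelled as 100–300 ms saturation to a
  30° sentinel (beyond the 25° linear range); saccades as conjugate
  (same-sign) raised-cosine transients of 30 ms whose monocular peak
  velocity is 12× the vergence peak, so the order-of-magnitude
  identification rule is exercisable. Trials are emitted in volts through
  per-subject inverse calibrations (gains ~N(10, 0.5) deg/V).
* **BOLD runs.** 210 GM voxels split into seven 30-voxel ROI footprints,
  50 CSF and 60 WM voxels, baseline 1000. ROI voxels carry baseline ×
  (1 + psc/100 × response) where the response is the HRF-convolved boxcar
  normalized so the analysis-side PSC definition (trim 5, shift 4 s)
  recovers the injected value exactly on clean data. All voxels add linear
  + 0.005 Hz sinusoidal drift (amplitude 5), two shared "physiological"
  sinusoids at 0.2 and 0.3 Hz (GM loadings ~N(0, 3); CSF/WM loadings twice
  as strong, so tissue-PC regression can find and remove them), and white
  noise (σ = 3, i.e. 0.3% of baseline — chosen so single-voxel design
  correlations fall in the 0.4–0.8 range typical of clearly activating
  block designs). Motion is a slow random walk (0.02 mm / 0.01° steps)
  with optional injected spikes.
* **Cohorts.** Group means: peak velocity 20/11/16 °/s (BNC / CI-pre /
  CI-post, SD 3/2.5/2.5) — field-typical values for 4° convergence steps
  with a training effect restoring CI toward control levels; PSC means
  1.2/1.0/0.8% (FEF/PPC/CV) in BNC, scaled to ~45% in CI-pre and ~80%
  in CI-post, Broca 0 throughout; CISS targets 6/32/14 (straddling the
  21 cutoff); clinical baselines from the printed CI values (NPC
  13.4 ± 5.6 cm, base-out range 14 ± 4.5Δ, near phoria 9.0 ± 1.4Δ
  exophoria) with improvements of ~7 cm, ~11Δ and ~3.5Δ after training.
  CI-post draws share the pre-training subject latents plus small paired
  jitter, so paired tests see true pairing.
* **Brain–behavior link.** `behavior_bold_correlation` targets the *pooled*
  across-subject Pearson correlation between peak velocity and ROI-pair
  PSC. Because group means co-vary (slower groups are also less active),
  the pooled correlation exceeds the within-group one; the generator solves
  for the within-group latent correlation from the group-mean geometry and
  the configured spreads so that the pooled value hits the target (0.6 by
  default; 0 for the Broca control). If an extreme target demands an
  infeasible within-group correlation it is clamped to ±0.999 with a
  warning.

**What the generator does not emulate:** eye-plant biomechanics or neural
control dynamics (positions are kinematic profiles), MRI physics, spatial
structure (voxels have no smoothness or anatomy; ROI masks are exact
footprints), physiological noise beyond two shared sinusoids, task-correlated
head motion, and slice timing. Passing recovery tests therefore demonstrate
the correctness and calibration of the *analysis* under the stated noise
model, not robustness to every artifact of real recordings.

## Problem sizes in the test and acceptance runs

Recovery checks use the study-scale design throughout (70-volume runs, 30
voxels per ROI): 20 subjects per injected PSC level, 10-subject grids with
20 trials each for peak velocity, and 100 cohort seeds for the regression
recovery. These sizes give stable Monte-Carlo estimates while keeping the
whole suite and the acceptance script in the seconds range.

## Known limitations

* The fixed r ≥ 0.4 pooling threshold ignores effective degrees of freedom
  and autocorrelation; PSC is threshold-dependent (the longitudinal
  comparison is valid because the threshold is constant across conditions).
* Max-based peak velocity is upward-biased under trace noise (see above).
* The CISS item model (independent binomial items) matches totals, not
  inter-item structure.
* Statistical power at n = 4 paired / 7 vs 4 unpaired is what it is; the
  generator's effect sizes make the battery significant in typical draws,
  matching the modelled study's qualitative findings, but individual seeds
  can and do fail significance on single measures.
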