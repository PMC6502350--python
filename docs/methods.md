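# Methods

`cvrfn` implements a voxel-wise analysis of how impaired cerebrovascular
reactivity (CVR) dampens task-evoked BOLD-fMRI activation, together with a
synthetic phantom generator that makes every stage verifiable by parameter
recovery. This note documents the models, the defaults and why, the
numerical choices, and what the synthetic data does and does not emulate.

## The experiment being modelled

A subject undergoes two scanning sessions that differ only in the clamped
end-tidal CO₂ (PetCO₂) baseline:

* **normo** — PetCO₂ clamped at the subject's resting value (default
  38 mmHg; resting values are subject-specific in reality and configurable
  here),
* **hyper** — PetCO₂ clamped ~6 mmHg above resting, which consumes part of
  the cerebrovasodilatory reserve.

Each session contains a **CVR run** (200 volumes, TR 2 s: 100 s clamp, then
a pseudo-square +10 mmHg PetCO₂ step held for 80 s, then return to
baseline) and a **task run** (135 volumes: four 30 s finger-tapping blocks
alternating with 30 s rest, CO₂ held constant). Because vasodilation is
nearly saturated ~10 mmHg above resting, the hypercapnic baseline roughly
halves the measurable CVR, and task responses shrink with it — voxels that
are confidently supra-threshold under normocapnia can drop below the
significance threshold: *false-negative* activation with intact neurons.

## Generative model (module `synth`)

The phantom is a 24×24×12 grid (3 mm isotropic) containing nine equal
block-shaped regions (216 voxels each) for the motor network: bilateral
precentral and postcentral gyri, frontal opercula, cerebella, and the SMA.
Equal region sizes make the analysis-mask mean CVR equal to the unweighted
region average, which keeps whole-brain summaries interpretable.

Per voxel, the CVR run is

S(t) = S₀ · [1 + (CVR/100) · (PetCO₂(t − δ) − PetCO₂_baseline)] + S₀·d(t) + ε(t)

and the task run is

S(t) = S₀ · [1 + (Δ%/100) · r(t)] + S₀·d(t) + ε(t)

with S₀ = 800 (arbitrary scanner units; all estimates are
scale-invariant), δ the voxel's hemodynamic lag (uniform on [0, 8] s,
quantised to the 1 s CO₂ sampling grid so exact recovery is testable),
r(t) the unit-peak HRF-convolved block regressor (identical to the one the
GLM fits), ε white Gaussian noise with sd 1% of S₀ by default, and d(t) an
optional order-2 Legendre drift (amplitude 0 by default; the CVR
regression model contains no drift terms, so simulated drift is exercised
in dedicated tests rather than in the default cohort).

Ground-truth regional values (CVR in %/mmHg and task Δ% per condition) are
given by a built-in table of healthy motor-network group means; the
hypercapnic columns encode the ~50% CVR reduction as condition-specific
slopes rather than an explicit saturation curve, since the analysis
estimates condition-wise linear CVR, not the saturation nonlinearity.

The CO₂ step uses 6 s linear ramps (real pseudo-square targeting is not
instantaneous; the exact ramp time is not critical because the regression
is linear in the trace whatever its shape).

**What the phantom does not emulate:** head motion, slice-timing offsets,
spatial distortions and smoothing, cardiac/respiratory physiological
noise, temporally autocorrelated thermal noise, partial-volume effects,
or within-region heterogeneity of CVR/Δ%. Passing recovery tests therefore
demonstrates the correctness of the estimation machinery under the stated
noise model, not robustness to real-scanner artefacts. Independent Gaussian
noise was chosen deliberately: it keeps OLS standard errors exact, so t
statistics have a known null distribution and calibration is testable.

## CVR mapping (module `cvr`)

Per masked voxel (mask: grey+white tissue probability, capped at 1,
≥ 0.8):

1. **Percent normalisation** about the voxel's mean over the initial
   clamp window (first 100 s). The baseline window is the only part of the
   run guaranteed stimulus-free at every lag.
2. **Temporal smoothing**: zero-phase 4th-order Butterworth low-pass
   (cutoff 0.1 Hz — well above the stimulus fundamental ~0.0025 Hz, so the
   step survives while high-frequency noise is removed), then robust loess
   (span 10% of run length, 2 bisquare iterations).
3. **Lag estimation**: Pearson cross-correlation against candidate
   regressors built by resampling the CO₂ trace at volume midpoints
   shifted by each lag on a ±10 s, 1 s grid. Ties break toward the
   smallest |lag|, then negative. Zero-variance voxels get lag 0 and a
   flag; window-boundary lags are flagged as saturated. Positive lag means
   BOLD follows CO₂.
4. **Regression**: OLS of percent signal on the lag-aligned regressor with
   intercept; the slope is CVR (%/mmHg), its t statistic forms the CVR
   t-map (capped at 10⁶, reached only for noise-free data).

Two numerical choices deserve emphasis:

* **The regressor is smoothed with the same operator as the BOLD data.**
  Smoothing only the signal attenuates it relative to the regressor and
  biases the slope low. The low-pass filter is linear and the robust loess
  is affine-equivariant (its bisquare weights depend on residual ratios
  that are invariant under affine maps of the series), so applying the
  identical operator to both sides leaves the slope exactly unbiased —
  noise-free phantoms are recovered to machine precision.
* **Candidate regressors are shift-resampled from the 1 s trace**, not
  interpolated from the TR-sampled regressor, so integer-second lags are
  represented exactly. Outside the trace the clamped edge value is held
  (physically, the clamp precedes and follows the scan).

Whether lag should be estimated on smoothed or raw series is not an
externally fixed convention; smoothing first is the default
(`CvrConfig.smooth=False` disables all smoothing).

## Task GLM (module `glm`)

The task regressor is the block boxcar at 0.1 s resolution convolved with
a canonical double-gamma HRF (peak 6 s, undershoot 16 s, unit dispersions,
undershoot ratio 1/6), sampled at volume midpoints and **normalised to unit
peak**, so on percent-normalised data the task coefficient is directly the
task-evoked percent signal change (Δ%fMRI). Unit peak — rather than unit
boxcar amplitude — was chosen because it makes the coefficient equal the
plateau response actually present in the data; the alternative convention
would rescale every Δ% by the convolution peak.

The design is [task, nuisance columns, Legendre drift (order 2 by
default), intercept]; rank deficiency raises an error naming the redundant
columns. Percent normalisation uses the first rest block (the first 30 s,
which precedes the first task onset, so the task regressor is exactly zero
there). Voxels are fitted by vectorised OLS; t is the task coefficient
over its standard error (no autocorrelation correction — the noise model
is white, and the reference analysis is plain least squares).

Significance uses strict exceedance t > 3.43 (configurable); the
"combined" mask is the union of the two conditions' significant voxels.

## ROI statistics (module `roi`)

Regional summaries report mean CVR, mean Δ%fMRI and mean t per region,
condition and modality. The default voxel set for the summary table is the
combined significant-voxel set (the set over which the two conditions are
directly comparable); `voxel_set="all_masked"` switches to whole-ROI
means. The two differ in a known way at the default noise level: selecting
voxels by task t correlates with the voxel's noise in Δ%, so
combined-significant Δ%fMRI means carry a positive selection bias
(~+0.04 at 1% noise). CVR means are immune (truth is constant within a
region and CVR noise is independent of the task run), so either voxel set
recovers the embedded CVR truth. Recovery checks of Δ%fMRI therefore use
whole-ROI means.

Condition differences use a two-sided paired t-test with Bonferroni
correction (factor = 9 regions × measures tested, reported in the output);
a repeated-measures ANOVA over two conditions is mathematically the paired
t-test and is exposed as an alias. The ROI-mean CVR-vs-activation
association is simple OLS with CVR as the independent variable (a
"stepwise" selection over a single predictor degenerates to this), run per
condition and pooled, for both the (Δ%, Δ%) and (t, t) pairings.

False-negative voxels are those significant under normocapnia but not
hypercapnia. A second rule flags activated voxels with Δ%fMRI < 1 despite
CVR > 0.15 — task responses near the detection limit even with preserved
reactivity.

## Cohort orchestration (module `pipeline`)

`run_cohort` simulates and analyses `n_subjects` (default 17) independent
subjects. Per-subject seeds are the first state word of
`SeedSequence([master_seed, subject_index])` (31-bit), and each artifact
(phantom, each run) draws from its own documented child stream, so cohorts
are bit-reproducible and subjects do not change when the cohort grows.
Outputs: per-subject NIfTI maps, CSV tables (regional summaries, group
mean ± sd with the n−1 denominator, significant-voxel counts, paired
tests, regressions, false-negative summary) and a JSON run summary.

## Problem sizes used in the checks

Noise-free exactness and calibration checks run on 12×12×6 or single
default-grid phantoms; group-recovery checks run the full default cohort
(17 subjects × 2 conditions × 2 runs on the 24×24×12 grid, ~1,944
analysis voxels), which completes in a few minutes on one CPU. The null
calibration aggregates 7,200 null voxels over 50 seeds; the
direction-of-effect check uses 10 master seeds of 2-subject cohorts (task
stage only). These sizes were chosen as the smallest at which the targeted
group effects are comfortably resolved.

## Known limitations

* The noise model is white; real BOLD noise is autocorrelated, so real-data
  t values would be optimistic without prewhitening (out of scope).
* Lag is constant per voxel and on the 1 s grid; dispersion of the vascular
  response is not modelled.
* The CVR model is linear in PetCO₂ per condition; the underlying
  saturation nonlinearity is only represented across conditions.
* Spatial preprocessing (motion correction, normalisation, smoothing) is
  absent by construction; the package analyses already-aligned data.
* Regional truth values are single numbers per region; between-subject
  variability enters only through noise, so group sds underestimate
  biological heterogeneity.
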