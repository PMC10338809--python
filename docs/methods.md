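# Methods

## The measurement chain

The quantity of interest is the time course of gadolinium enhancement in
the inferior dural lymphatic vessel, which lies between the inferior edge
of the superior sagittal sinus and the falx cerebri. On contrast-enhanced
T2-FLAIR the vessel is conspicuous because the inversion pulse nulls CSF
and the sinus is dark (flow void plus T2 loss from concentrated
intraluminal gadolinium), while dilute gadolinium in the vessel *raises*
signal through mild T1 shortening.

Measurement proceeds exactly as it would on patient data:

1. a rectangular ROI (default 3 rows × 5 columns, vessel-scale at 0.52 mm
   in-plane voxels) is centered on a seed voxel and replicated on all
   slices;
2. per time point, all ROI voxels are pooled across slices and the robust
   maximum — the 98th percentile with linear interpolation at position
   `0.98 (n−1)` — is taken; the percentile convention is stated because
   toolkits differ;
3. the resulting signal is divided by the median intensity inside the
   brain mask of the precontrast volume, giving a dimensionless curve
   `S(t)` in units of the precontrast brain median;
4. five semi-quantitative parameters summarize the curve (see README);
   the washout slope is recorded as missing, not zero, when the peak falls
   on the last acquisition or the curve never exceeds baseline — averaging
   in zeros would bias cohort summaries;
5. each metric is regressed on each covariate (OLS); for a single
   predictor the Pearson-correlation t-test and the regression F-test
   coincide, and we report r, two-sided p on n−2 df, and a three-band
   p classification (p<.05, .05≤p<.1, p≥.1). Lesion volume enters as its
   cube root. No multiple-testing correction is applied by default
   (a Benjamini–Hochberg option exists but is off).

Pooling all slices' ROI voxels into one percentile (rather than a
per-slice percentile followed by a maximum) is a deliberate reading of
"robust maximum of all voxel intensities at that time point"; it is also
the variant with the cleaner noise behaviour, since the percentile sees
~150 voxels instead of 15.

## Ground-truth curve model

Each synthetic subject's lymphatic curve is piecewise linear in normalized
units: baseline `s0_lymph`, linear rise to `s0_lymph (1 + e_peak)` at
`tau_peak` minutes, then linear decay at `s0_lymph · w_decay` per minute.
The model is intentionally the simplest shape for which every reported
metric has a closed form — the metrics themselves are piecewise-linear
summaries, so a gamma-variate or pharmacokinetic model would add
parameters without adding testable structure. Generation enforces
`w_decay (t_guard − tau_peak) < e_peak` (signal never decays below
baseline within the acquisition window plus a 6-minute jitter margin).

## Acquisition schedule

One precontrast scan at t = 0 and seven postcontrast scans at nominal
delays 2.5/5/7/9/17/20/35 min. Realized delays add zero-mean Gaussian
jitter, SD 1.0 min for the four wash-in acquisitions and 2.2 min for the
three late ones — the patient-compliance variability reported for this
protocol; a draw that breaks strict ordering is rejected wholesale.
The reported mean *realized* last delay (33.4 min) sits ~1.6 min below
nominal; we model jitter as unbiased and do not reproduce that systematic
drift, so our realized grids center on the nominal times.

## Synthetic cohort

Covariates are truncated normals with the study population's means and
bounds (SD = range/4 where no SD was printed), EDSS rounded to 0.5 steps,
lesion load log-normal matched to the published median and range, BPF
truncated normal with mean 0.81 on [0.67, 0.92] (the printed bracket reads
as a range, not an SD), phenotype 65 % RRMS. Only `e_peak` is directly
coupled to BPF: `e_peak = mean + b·(bpf − bpf_mean) + ε`, with the
coupling `b` set so that corr(BPF, e_peak) equals the published
peak-enhancement correlation (−0.57). AUC and wash-in inherit their
correlations structurally through the curve. The coupling uses the
*realized* SD of the truncated BPF draw — with bounds at ±2 SD the nominal
parameter would understate it and dilute the correlation by ~10 %.

Per-subject randomness (jitter, rendering noise) comes from NumPy
`SeedSequence` substreams of the single cohort seed, so cohorts, images
and sidecars are bit-reproducible.

## Calibration

`calibrate_generator` matches the *measured* metrics — formulas applied to
noiseless curves sampled on the nominal schedule, via a deterministic
60 000-subject Monte-Carlo oracle with a fixed internal seed — to target
cohort statistics, one knob per target (damped ratio/secant iteration,
stopping when all knobbed moments are within 1 %):

| target            | knob                  |
|-------------------|-----------------------|
| P_enh mean / SD   | e_peak mean / total SD |
| T_max mean / SD   | tau_peak mean / SD    |
| washout mean / SD | w_decay mean / SD     |
| AUC mean          | s0_lymph mean         |

Matching measured rather than continuous metrics matters: T_max snaps to
the sparse grid, the peak is sampled slightly off its true time, and the
trapezoid clips the kink at the peak.

**The wash-in slope is over-determined.** Once the AUC target fixes the
curve amplitude (`s0_lymph ≈ 0.83`), the mean wash-in slope is bounded by
`s0 · E[e_peak] / T_1 ≈ 0.375 min⁻¹`, and approaching that bound requires
essentially every `tau_peak < T_1 ≈ 2.5 min` — which contradicts a mean
measured time-to-peak of 6.7 min. The published triple (wash-in 0.35,
T_max 6.70, AUC 25.42) is therefore not jointly attainable under this
curve model on this schedule; the calibrated generator realizes the T_max
spread as genuinely late peak times and lands at a wash-in mean of
≈0.23 min⁻¹. A plausible reading of the original data is that its T_max
spread was partly measurement-noise argmax scatter along a near-flat
post-peak plateau rather than true peak-time spread; reproducing that
would require calibrating T_max against noisy rather than noiseless
curves, which the curve-level contract deliberately avoids. The residual
is reported in the calibration diagnostics (and `strict=True` refuses to
return such a config). The same tension propagates to the BPF–wash-in
correlation: the `tau_peak` heterogeneity needed for the T_max target
dilutes corr(BPF, wash-in) to ≈ −0.31 versus the published −0.56, while
corr(BPF, AUC) ≈ −0.55 and corr(BPF, P_enh) ≈ −0.57 are reproduced.

## Phantom and rendering

The coronal head phantom (10 slices × 256 × 256, proportions scale to
smaller grids) contains parenchyma, a subarachnoid CSF rim, the
interhemispheric fissure, the sinus at its apex, the 2-voxel-tall inferior
lymphatic ribbon at the sinus base, the falx below it, and unmeasured
superior lymphatic vessels lateral to the sinus.

*Direct mode* (default) writes intensities as fractions of the parenchyma
baseline — parenchyma 1, CSF/sinus 0.01, falx 0.7, lymph voxels following
the subject's true curve — so normalization is exactly the identity on
noiseless phantoms and extraction errors are attributable to the
measurement chain alone. *Physical mode* renders every tissue through the
inversion-recovery spin-echo magnitude equation
`PD·|1 − 2e^(−TI/T1) + e^(−TR/T1)|·e^(−TE/T2)` at TR/TE/TI =
3000/90/1200 ms, with gadolinium shortening both relaxation times
(r1 = 3.9, r2 = 5.5 s⁻¹mM⁻¹) and the lymph concentration proportional to
the fractional enhancement (0.5 mM at peak, on the T1-dominated branch);
CSF T1 sits at the sequence's null point. Physical mode exists to check
that the FLAIR contrast mechanism (CSF/sinus suppression, mild-gadolinium
enhancement, T2 collapse at high concentration) behaves correctly; it is
not used for the recovery experiments because the signal-versus-
concentration map is nonlinear and would confound curve-shape recovery.

Noise is Rician — `sqrt((S+n₁)² + n₂²)` with i.i.d. Gaussian quadrature
noise — at the default SD of 2 % of the parenchyma baseline. A known
consequence, measured by the recovery experiments rather than hidden: the
98th percentile of a noisy voxel pool is positively biased (≈ +2 noise SDs
here), and because the *relative* bias is larger at the dim baseline than
at the bright peak, the recovered grand mean of P_enh sits ≈ 7 % below its
noiseless calibration (≈101 % vs 109 %), and AUC ≈ 3 % low. Slope metrics
are differences of equally biased points and are nearly unaffected.

## What the synthetic data does and does not establish

The generator reproduces the *statistical* structure of the study cohort —
covariate moments, metric moments, BPF coupling, acquisition-timing jitter,
magnitude-MR noise at the ROI — so passing recovery tests shows the
measurement chain is unbiased (or has quantified bias) under those
conditions. It does not emulate motion between time points, registration
error, partial-volume variation in vessel conspicuity, B1/coil
inhomogeneity, lesions, or real cortical anatomy; recovery results
therefore bound pipeline error, not total in-vivo error. Brain and lesion
segmentation are upstream of this package: covariates (including BPF and
lesion load) are taken as inputs.

## Numerical conventions and edge cases

* Percentile: linear interpolation between order statistics; median of an
  even count: mean of the two central order statistics.
* Argmax ties (plateau curves): earliest time wins.
* Curve times must be strictly increasing with t = 0 first; S_0 = 0 makes
  enhancement undefined and is an error, not a NaN.
* ROI windows: odd sizes symmetric about the seed, even sizes extend one
  voxel toward increasing index; clipped at image edges; an ROI outside
  the brain mask warns but proceeds (the vessel is extra-parenchymal).
* Truncated sampling: vectorized rejection with a 1 000-round budget
  (exceeding it is a generation error); the washout rate alone uses
  inverse-CDF truncated-normal sampling because its upper bound is
  subject-specific (the never-below-baseline constraint) and can truncate
  extremely.
* All signals are dimensionless fractions of the precontrast brain
  median; slopes are min⁻¹ in those units; AUC integrates the
  baseline-subtracted signal from 0 to the last acquisition (the
  integrand and limits are a stated convention — alternatives such as raw
  signal or fractional enhancement rescale AUC but do not change its
  correlations).

## Problem sizes

Recovery experiments use 50 rendered image cohorts and 200 curve-level
cohorts of 20 subjects (the study's sample size), and 1 000 replicates for
the null false-positive-rate check — sizes at which replicate-mean
standard errors are comfortably below the comparison tolerances (e.g.
SE ≈ 1.5 % for the P_enh grand mean, ≈0.012 for mean correlations).
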