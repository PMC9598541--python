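# Methods

This note documents the models, defaults and numerical choices behind
cstperf, and what the synthetic-data tests do and do not establish about
real data.

## Compartment model and CBF measures

The analysis unit is the compartment: (structure, subdivision, hemisphere)
with structures {cortex, striatum, thalamus} and six functional subdivisions
{prefrontal, rostral motor, caudal motor, parietal, occipital, temporal} —
36 compartments per examination. Atlases arrive as integer label volumes
(NIfTI) with a TSV label table; probabilistic 4-D atlases are reduced to
max-probability labels with a configurable floor (default 25%; ties go to
the lowest label id, for determinism). Merge rules collapsing seven-part
striatal/thalamic connectivity parcellations to the six subdivisions are
total mappings validated at apply time; the cortical grouping of a standard
anatomical parcellation into the six subdivisions is shipped as a documented
default table (`DEFAULT_AAL_CORTICAL_GROUPING`) but is a package choice —
users with their own grouping supply their own table. Hemisphere assignment
comes from the label table; labels without one can be split on the world
x = 0 plane (RAS+), with midline voxels dropped to background.

A-CBF is the arithmetic voxel mean of the quantified CBF image
(ml/100 g/min) over a compartment. R-CBF divides by the whole-brain-cortex
mean, defined here as the voxel-weighted mean over the union of the twelve
cortical compartments (not a mean of means); this makes
`r_cbf * whole_cortex_mean == a_cbf` an exact identity used as a test
invariant. Volumes are consumed already quantified, co-registered and
normalized; no smoothing or partial-volume correction is applied, and
non-positive voxels (ASL noise) are counted but included in means by default
(a `exclude_nonpositive` switch exists). Whole-image artifact QC is an
upstream boolean flag, not an automated detector.

## Normative comparison

Controls must match the patient's scanner and sedation status exactly; the
age window starts at ±25% of the patient's age and doubles until the
minimum cohort size (default 10) is reached, capped at the whole filtered
pool. The window policy is a package choice: no principled tolerance exists
for pediatric CBF age-matching, and the stepwise widening makes the
selection deterministic and auditable.

With one value per patient per compartment, the comparison is the
single-case t-test (Crawford–Howell): a pooled-variance two-sample t-test
with n₁ = 1, df = n − 1, two-sided. Minimum three controls and nonzero
control variance are enforced. No multiple-comparison correction is applied
by default, matching the stated α = 0.05 decision rule; a Benjamini–
Hochberg flag is available but off. Classification is increase/decrease/
normal by the p < α cut and the sign of (patient − control mean).

## Circuit coincidence and group accounting

A circuit pattern is the maximal subset (≥ 2) of structures sharing
subdivision, hemisphere, measure and direction; subsets of an emitted
pattern are not emitted. Coincidences with mixed directions are not
circuits; they are reported separately as discordant strata. Bilateral
homologous changes count once per hemisphere. Group summaries count changed
compartments out of 36 × n examinations, by direction and structure, with
exact fractions retained and percentages rounded to integers for reports.

Fisher's exact test is computed by exact integer hypergeometric
enumeration: the two-sided p sums the probabilities of all tables with the
observed margins whose point probability does not exceed the observed one
(comparison done on integer numerators, so ties are exact). The sample odds
ratio a·d/(b·c) is reported with 0/0 → NaN and x/0 → ∞.

The donut model maps each compartment status to a cell (ring = structure,
outside→inside C, S, T; sector = subdivision, clockwise from the top;
red/blue/green = increase/decrease/normal), one chart per hemisphere and
measure. The chart model is the canonical, testable artifact; matplotlib
rendering is a thin layer over it.

## EEG: EMG onsets and jerk-locked back-averaging

Onset detection: 4th-order Butterworth high-pass (20 Hz, zero-phase),
rectification, causal moving-average smoothing (20 ms), threshold at
baseline median + 5·MAD (floored at 1% of the envelope's dynamic range so a
silent background cannot collapse the threshold to numerical residue).
Supra-threshold runs separated by < 100 ms are merged (the noise-like EMG
carrier fragments one burst), with the 30 ms minimum duration counted on
supra-threshold samples only, and a 500 ms refractory period. Because a
threshold crossing is systematically late on a ramping envelope, the onset
is refined in two stages: a linear fit of the envelope's rising flank
extrapolated to zero anchors a likelihood scan in which the high-passed
signal is modeled as zero-mean Gaussian whose sd ramps from the background
level to the burst amplitude; onset and rise time are scanned on a grid
(rise 5–40 ms) and an abrupt-step hypothesis is accepted when it beats the
best ramp by a clear margin. The burst amplitude entering the variance model
is calibrated as envelope-peak/0.8; this slight overestimate empirically
centers the onset error distribution. On the default synthetic bursts at
amplitude SNR 10 the detector is unbiased to ~1 ms with ~94% of onsets
within ±5 ms — close to the information limit for a 40 ms linear-rise
burst in band-limited noise.

Back-averaging: EEG is re-referenced to the common average (configurable),
epochs of −500…+500 ms around each EMG onset are baseline-corrected by the
mean of −500…−300 ms, and averaged. The peak is the signed extremum of
largest magnitude in −200…0 ms; its latency is negative when the cortical
transient precedes the EMG. These windows are package choices consistent
with premotor sharp waves leading EMG by 20–60 ms. Interval statistics
(median, IQR, min, max of successive complex-to-complex differences)
summarize discharge periodicity.

## Synthetic data

The generator defines the study conditions; its defaults are fixed.

**Atlases.** Block parcellations on a ≥16³ grid (default 32³): hemispheres
split the x axis, structures occupy y slabs, subregions occupy z chunks
with seed-jittered widths so compartment sizes differ; two y rows stay
background.

**Control CBF.** Cortical mean follows a saturating maturational curve
(28 ml/100 g/min at birth → 58 asymptotically, time constant 30 months).
The subcortical/cortical ratio holds at 1.5 through the first 12 months,
then decays exponentially (time constant 48 months) to 1.0 — at 6 months it
is exactly 1.5, by 15 years within 2% of 1. Between-subject variation is a
mean-one log-normal factor (CV 0.15; log-normal keeps CBF positive) common
to all compartments, plus a per-compartment log-normal jitter (CV 0.05)
giving R-CBF a realistic between-subject spread; voxel noise is Gaussian
(sd 5 ml/100 g/min). The default pool is 232 children, ages 3–186 months,
two scanners, sedation below 48 months. Cohort dispersion values are free
parameters of the generator — no quantitative dispersion is available to
pin them — and are exposed in `CohortSpec`.

**Patients.** A control draw of the requested age whose chosen compartments
are scaled voxel-wise by multiplicative factors. The default ictal effect is
2.0 — the magnitude of stroke-like ictal hyperperfusion — which is ≈6
control SD at the default dispersion. This deliberately exceeds the ≥3 SD
floor assumed by the recovery tests: at ≈3 SD the single-case test has only
~80% per-compartment power at n = 20 controls, so a triple-structure circuit
could not reach a 95% recovery rate at that floor; ≈6 SD gives per-structure
power ≈99.9%.

**Polygraphy.** 19 EEG channels (10–20 layout) + 2 deltoid EMG channels at
1024 Hz. Clinical review EEG is often stored at 256 Hz, but EMG onset
localization to a few milliseconds requires the EMG interference band
(20–400 Hz here) to be properly sampled, so the generator defaults to a
research-polygraphy rate. Background EEG is 0.5–4 Hz colored noise
("slow and depressed"; sd 20 µV). Each complex is a negative sharp wave
(hann, 120 ms, 90 µV peak at the maximal channel) with a fixed zero-sum
topography — central-parietal negativity, left predominant, compensating
frontal positivity (phase reversal) — followed 60 ms later by a lower slow
wave (500 ms) with optional superimposed 20 Hz fast rhythms. The zero
channel sum makes the topography invariant under common-average
re-referencing, so the injected amplitude is recoverable from the CAR
back-average. EMG bursts start a fixed latency (default 40 ms, snapped to
the sample grid and recorded as ground truth) after each complex peak, with
a diamond envelope (40 ms rise, 110 ms fall) multiplying a unit-amplitude
carrier (band-limited noise normalized by its Hilbert envelope, so the
instantaneous amplitude follows the diamond exactly and the onset is
identifiable). Envelope peak 100 µV over background sd 10 µV defines
amplitude SNR 10. Presets: SSPE early (intervals 5–7 s), SSPE late (2–3 s),
lateralized PDs (left-hemisphere topography, not zero-sum), clustered
spasms (diffuse slow wave, bilateral asymmetric bursts), and a null
background. Lateralized presets are analyzed on the raw referential
montage, since CAR would smear a one-sided topography across channels.

## What the synthetic tests do and do not show

Passing tests establish the pipeline's arithmetic (compartment accounting,
merge conservation, ratio identities), the statistical calibration of the
single-case test under the generator's noise model, the recovery of
injected effects several SD in size, and the correctness of the EEG
averaging machinery. They do not establish performance on real ASL data —
no registration error, partial-volume effects, atlas mismatch in diseased
or infant brains, scanner-specific quantification bias, or motion — nor on
real EEG with artifacts, variable complex morphology, or per-event latency
jitter. The simulated type-I error, in particular, is exact only under the
generator's log-normal/Gaussian noise; heavier-tailed real data would
inflate it.

## Simulation sizes and numerics

Test simulations use a 24³ fixture grid, cohorts of 20 controls, 1000 null
replicates for calibration and 500 for circuit recovery; these sizes give
binomial standard errors well inside the asserted bands. Affine equality is
checked to 1e-4; ROI means are accumulated with `np.bincount` (one pass,
deterministic); max-probability ties take the lowest label id; the null
calibration redraws the control cohort every replicate so the reported
type-I error is unconditional rather than conditional on one cohort draw.
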