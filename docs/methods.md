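# Methods

## Setting and signal model

The package analyses epicardial contact mapping of beating, ex-situ
perfused hearts. A rectangular array of 120 electrodes (default 10 rows x
12 columns, 2 mm pitch, 0.6 mm electrode diameter) records unipolar
extracellular potentials referenced to a distant indifferent electrode,
sampled at 2 kHz with 16-bit conversion over a +/-32 mV full scale
(0.977 uV per count) and 0-500 Hz bandwidth. Each mapping position yields
5 s of 120-channel signal; the heart is paced at >= 70 bpm, so a position
contains several paced beats.

The actual row/column arrangement of the 120 electrodes on the clinical
array is not public; 10 x 12 with row-major channel order is this
package's convention and is configurable through the recording metadata.

## Electrogram annotation

* **Beat segmentation.** When pacing stimulus times are known each
  stimulus anchors a beat; otherwise anchors are peaks of the smoothed
  (20 ms) cross-channel mean absolute signal. The analysis window is
  [-50, +250] ms around the anchor, clipped at midpoints between anchors.
  The +250 ms tail is sized so that even the widest deflections the
  pipeline generates (flat-slope ischemic electrograms, sigma up to
  ~60 ms) keep both extrema inside the window.
* **LAT** is the time of the minimum central-difference first derivative
  inside the window (ties: earliest). No extra smoothing is applied: the
  signal is already band-limited to 0-500 Hz at 2 kHz sampling, and
  smoothing would bias the steepest-deflection definition.
* **Artifact blanking.** Samples from 5 ms before to 10 ms after each
  stimulus are excluded from both the LAT search and the peak-to-peak
  measurement. The leading guard exists because a biphasic stimulus
  artifact has a lobe before its centre; without excluding the artifact
  from the voltage measurement, low-amplitude (ischemic) electrograms
  would be dominated by the artifact's amplitude rather than their own.
* **Voltage** is max minus min over the un-blanked window; **slope** is
  the central-difference derivative at the LAT sample (one-sided at trace
  boundaries, flagged).
* **Exclusion rules** (flagged, never silently dropped): a channel/beat is
  `excluded_flat` when its peak-to-peak is below max(3 x estimated noise
  SD, 0.05 mV), with the noise SD estimated robustly from the median
  absolute first difference; `excluded_artifact` when > 1% of window
  samples sit at the ADC rails or the annotated slope is positive.

## Conduction analysis

Per beat, accepted LATs form a [rows x cols] map. Conduction times are
absolute LAT differences over the 4-neighbour adjacency (diagonals are
excluded because the 12 ms block criterion is defined for adjacent
electrodes at 2 mm). Block is Delta-CT >= 12 ms (inclusive); prevalence is
the flagged fraction of all evaluable pairs, in percent. Velocity inverts
the central-difference time gradient at interior electrodes with four
present neighbours: CV = 1/|grad T|, direction along the gradient. The
exact "discrete velocity vectors" algorithm used clinically is described
elsewhere and its neighbour sets/outlier handling are not reproduced here;
the gradient inversion is a documented stand-in that is exact for affine
activation surfaces (planar wavefronts), which is how it is validated.
Electrodes incident to a blocked pair are omitted from the velocity field
(configurable), so effective velocity is not contaminated by lines of
block. Beats are analysed separately and pooled; pooling order is not
specified by the underlying protocol, and per-beat-then-pool was chosen
because it needs no cross-beat registration.

## Substrate metrics and summaries

The low-voltage threshold is the 5th percentile of all accepted
peak-to-peak amplitudes pooled per ventricle across the whole cohort
(configurable to per-group), computed by linear interpolation between
order statistics (quantile position (n-1)q, the "type 7" convention) and
rounded half away from zero to an integer mV; at least 20 values are
required. A potential is low-voltage when strictly below the threshold.
Per-heart, per-ventricle summaries are medians over all accepted
potentials (all positions, all beats) for voltage and slope, the median of
pooled CV magnitudes, and pooled block prevalence. Electrode maps display
the per-electrode median across beats; histograms and summaries use every
deflection.

## Statistics

* **Exact Mann-Whitney U.** U counts pairs (x in group 1, y in group 2)
  with y < x, plus 1/2 per tie. For pooled sizes <= 14 the permutation
  null is enumerated over all C(n1+n2, n1) assignments of the pooled
  observed values (ties included, so exactness survives ties); the
  two-sided p is twice the smaller tail probability, capped at 1. At
  4-vs-4 this gives p = 2/70, 4/70, 8/70, 14/70, 24/70, 34/70, 48/70 for
  U = 0..6. Larger samples use the tie-corrected normal approximation with
  continuity correction. The doubled-tail definition was chosen over
  summing both tails of min(U, n1 n2 - U) because the two differ only for
  asymmetric tie patterns and doubling is the convention that reproduces
  the standard small-sample tables.
* **Pearson correlation** with the t-transform p (n-2 df); strength graded
  on |r|: < 0.3 weak, < 0.7 moderate, >= 0.7 strong. Grading on the
  magnitude (rather than the signed value) is an interpretation: negative
  coefficients of large magnitude are "strong".
* **Lactate trend**: slope between the first and last arterial sample
  after reperfusion, in uM/min; intermediate samples are ignored by
  definition.
* Pooled-variance t test and classical one-way ANOVA (for regional
  comparisons) are delegated to scipy. No multiple-testing correction is
  applied anywhere. Normality screening is left to the caller; the group
  comparison table defaults to the exact Mann-Whitney test for all EP
  parameters.

## Synthetic cohort generator

The generator is phenomenological, not biophysical: no monodomain or
ionic modelling, only the statistical structure the analysis assumes.

* **Deflection.** Each activation produces a derivative-of-Gaussian
  w(t) = -k (t - t0) exp(-(t - t0)^2 / (2 sigma^2)): biphasic RS
  morphology with closed forms A_pp = 2 k sigma e^{-1/2} and steepest
  slope -k at t0. Given amplitude and slope targets, sigma and k are
  solved exactly, so amplitude and slope are independently controllable
  and ground truth is analytic.
* **Activation.** Planar wavefronts (affine LAT, gradient magnitude 1/CV)
  or focal spread (distance/CV). Lines of conduction block add a fixed
  delay (default 18 ms) to the later-activated side; 18 ms guarantees
  every crossing pair exceeds 12 ms ground truth even after the planar
  step (<= 3.3 ms at >= 60 cm/s) is subtracted. Activation onset follows
  each stimulus by 15 ms plus one deflection width.
* **Nuisance terms.** White Gaussian noise (default SD 0.05 mV),
  sinusoidal baseline wander (0.2 mV at 0.5 Hz), a narrow biphasic pacing
  artifact (2 mV, 1 ms time constant) at each stimulus, pacing at 84 bpm,
  and 16-bit quantization of the summed signal.
* **Cohort structure.** Two groups of 4 hearts: severe ischemia (group 1)
  with per-ventricle voltage/slope medians 3.6 mV / 0.2 V/s (RV) and
  10.8 mV / 0.3 V/s (LV), versus mild ischemia (group 2) at 15.3 / 1.2 and
  23.6 / 1.1. Per-heart targets are the group median times a symmetric
  factor set {0.75, 0.95, 1.05, 1.3} (randomly assigned), so the median of
  per-heart medians equals the group median by construction. Per-electrode
  heterogeneity is log-normal (sigma_ln = 0.25, median-normalized); this
  dispersion is a free parameter of the generator, not a literature
  quantity. Group 1 positions carry a 4 x 5 low-amplitude patch
  (amplitude x 0.25, slope additionally x 0.5) and one block line; group 2
  conducts cleanly. The patch size (~17% of electrodes) is large enough to
  dominate the low-voltage tail while leaving the pooled group median
  within a few percent of its target. Wave direction is uniform per
  position and CV uniform in 60-100 cm/s. Default sampling design: three
  positions per ventricle (anterior/lateral/posterior); the real protocol
  maps many more positions in ~5 min, and position count is a pure
  problem-size parameter.
* **Perfusate and scores.** Arterial lactate is linear from a starting
  level (9.0 vs 8.0 mM at 20 min, SD 1.5) with group trends -24 vs
  -36 uM/min (SD 6 vs 14), small measurement noise, and venous samples
  offset by a fixed 0.2 mM uptake; electrolytes are physiological
  constants, with group 1 hyperkalemic (6.5 vs 4.5 mM). Contractility
  scores (three blinded raters, 1-5 per chamber) are a monotone map of the
  heart's per-ventricle voltage target plus rater jitter (SD 0.35,
  rounded, clipped) — so voltage-contractility coupling is strong by
  construction while lactate levels are independent of the EP phenotype,
  mirroring the qualitative pattern the pipeline is meant to detect.

## What passing tests do and do not show

The generator produces organized paced rhythm with smooth, identical-shape
deflections; real electrograms show fractionation, far-field components,
respiration/motion artifacts, electrode drop-out, and beat-to-beat
variability that are absent here. Recovery results on synthetic data
therefore validate the numerics of the pipeline (annotation, mapping,
velocity inversion, statistics), not its robustness to real-world signal
pathology. Group-level numbers from the simulated cohort (medians,
thresholds, correlations) characterize the generator's study conditions;
they are not reproductions of any measured animal data, which would
require the original recordings.

## Numerical choices and degenerate inputs

* LAT is reported on the sample grid (0.5 ms at 2 kHz) without sub-sample
  interpolation, preserving the argmin definition; planar-wave fixtures at
  80 cm/s have 2.5 ms inter-electrode steps (an integer number of
  samples), so conduction closed forms are recovered exactly.
* Ties in the LAT argmin break to the earlier time; ties in the exact test
  carry half-counts; percentile rounding is half away from zero.
* Missing data propagate as NaN: excluded electrodes leave holes in LAT
  maps, their incident pairs drop out of conduction-time sets, velocity is
  only evaluated where a full 4-neighbourhood exists, and empty summaries
  are NaN rows rather than errors.
* An empty conduction-time set yields NaN block prevalence; zero-variance
  correlation inputs yield a missing entry; degenerate ANOVA and t-test
  inputs raise.
* All randomness flows from explicit seeds (per-heart child seeds spawned
  from the cohort seed), so identical specs reproduce byte-identical
  cohorts.

## Problem sizes used in validation

The automated checks run the analytic fixtures at full size (one 120 x
10000-sample recording) and the stochastic cohort checks on scaled-down
cohorts of 4 + 4 hearts with one position per ventricle across 20 seeds;
the acceptance script runs one full default cohort (three positions per
ventricle). These sizes were chosen to exercise every code path at
realistic per-position scale while keeping the whole validation suite
quick to run.

## Known limitations

* The velocity estimator is exact only for locally planar wavefronts;
  curved or colliding wavefronts bias it (as does any finite-difference
  scheme at wave collisions).
* The 12 ms block criterion and the 5th-percentile low-voltage rule are
  conventions for 2 mm inter-electrode spacing; other geometries need
  re-derived thresholds.
* The exact test enumerates up to C(14,7) = 3432 assignments; beyond that
  the normal approximation is used rather than a faster network algorithm.
* Very flat ischemic deflections (slope below the noise-derived derivative
  floor) have effectively random LATs; they are retained as accepted
  potentials when their amplitude clears the flat-channel rule, which
  inflates apparent conduction block in severely ischemic tissue. This is
  a property shared with real mapping of injured myocardium.
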