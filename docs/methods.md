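# Methods

## Scope and approach

The package implements the quantitative analysis of a three-modality membrane
biophysics study: voltage-clamp fluorometry (VCF) of a K_V channel, membrane
probe spectroscopy, and ratiometric dipole-potential imaging.  Raw recordings
of this kind are usually not deposited, so the package pairs every analysis
stage with a synthetic-data generator and validates the whole chain by
closed-loop parameter recovery: data are simulated at known ground truth, the
pipeline analyzes them, and the recovered group statistics must match what
was put in.  `tevcf.reference` encodes one concrete reference study — control
vs C16-ceramide vs C16-glucosylceramide loading — whose group parameters act
as the generator ground truths.

## Electrophysiology model

The generator is phenomenological.  Pulse current at test potential V rises
single-exponentially to the steady state of the GHK-rectification × Boltzmann
model

    I_ss(V) = V · G_max · (1 − e^−(V−E_rev)/25) / (1 − e^−V/25) · B(V; V_1/2,G, k_G)

with B the Boltzmann curve; fluorescence rises double-exponentially toward
`ΔF/F_ss(V) = ΔF/F_max · B(V; V_1/2,F, k_F)` on top of a mono-exponential
photobleaching envelope, with an ohmic leak and Gaussian noise (additive on
current, multiplicative on fluorescence, matching detector physics at this
scale).  No Markov-state kinetics and no inactivation are simulated; the
fitted models require neither.

The removable singularity of the rectification quotient at V = 0 is handled
by a 4th-order series expansion of `1 − e^−V/25` for |V| < 0.5 mV; the two
branches agree to better than 1e−10 at the switchover.  The 25 mV constant is
part of the model equation, never a free parameter.

Default generator parameters (one simulated "control oocyte"):

| parameter | default | note |
|---|---|---|
| G_max | 0.1 µS | ≈5 µA at +40 mV, typical oocyte two-electrode scale |
| E_rev | −90 mV | K⁺ reversal in a low-K⁺ bath |
| V_1/2,G, k_G | −25.4, 9.6 mV | pore (G-V) activation |
| V_1/2,F, k_F | −42.5, 16.8 mV | voltage-sensor (F-V) activation |
| ΔF/F_max | 2% | typical TAMRA-type VCF signal; sign configurable |
| fast fraction | 0.9 | fast component of the fluorescence rise |
| τ maps | mono-exponential in V | e.g. current τ: 20 ms at −10 mV → 2 ms floor |
| leak | 0.002 µS | ohmic |
| bleach rate | 0.02 s⁻¹ | mono-exponential |
| current noise | 0.05 µA SD | white, per sample |
| fluorescence noise | 0.1% of baseline | = 5% of the 2% ΔF/F signal |

τ(V) voltage dependence is a synthetic convention (monotone speed-up with
depolarization); the simulator takes explicit per-voltage maps, so any
tabulation can be substituted.  Between-cell variability is an independent
Gaussian perturbation per parameter, truncated by redrawing into each
parameter's valid range — the simplest model that reproduces a target group
SEM (`SD = SEM·√n`).

## Trace processing conventions

- Gaussian low-pass filtering: kernel SD set so the −3 dB point equals the
  requested cutoff (default 1 kHz on 5 kHz data); zero-phase, DC gain 1.
- Leak: ordinary least squares of mean pulse current vs test potential over
  −140…−80 mV, where channel open probability is ≲0.3% for all fitted
  conditions; subtraction uses the commanded voltage per sample.  Estimating
  the leak this way is accurate to ~1% (the residual channel current at
  −80 mV); tests of exact closed-form identity therefore bypass estimation
  and subtract the known leak.
- Peak current: signed extremum within the pulse, excluding the first 2 ms
  (capacitive margin).  Before the extremum search the corrected trace is
  additionally smoothed to a 100 Hz measurement bandwidth: the peak of a
  non-inactivating current sits on the steady plateau, which the narrow band
  preserves, while an extremum over ~1250 wide-band noisy samples is biased
  upward by the largest noise excursion (at subthreshold voltages this bias
  reached ~0.1 µA and dragged the G-V midpoint by −2.5 mV; with the
  measurement bandwidth the residual bias is +0.3 mV).  Kinetics fits always
  use the full-bandwidth traces.
- Photobleach correction subtracts the most hyperpolarized sweep (no
  voltage-dependent signal there) and restores the baseline level; ΔF/F uses
  a 50-ms pre-pulse baseline window; steady state is the mean over the final
  10% of the pulse (≥4 slow time constants after onset), a window mean rather
  than a fit asymptote.
- All windows are configurable on `ProcessingConfig` and recorded with the
  processed output.

## Fitting conventions

- I-V fits: trust-region least squares with bounds (G_max > 0, k ∈ [1, 60],
  E_rev ∈ [−120, −40], V_1/2 ∈ [−100, +50]), initialized from a coarse grid
  over (E_rev, V_1/2, k) with G_max solved linearly; multi-start refinement
  is available and agrees with the single best grid start in ≥95% of noisy
  draws.  E_rev is weakly identified from suprathreshold-dominated data and
  may wander within its bounds; V_1/2 and k are insensitive to this.
- F-V fits: the steady-state ΔF/F values are normalized to the largest
  obtained value and fitted with a unit-amplitude Boltzmann.  Because the
  largest obtained value is ~0.99 of the true asymptote, this convention
  steepens the apparent curve slightly (k biased low by ~2%, midpoint by
  well under 1 mV) — an estimator property shared by any normalize-to-max
  analysis, left in place deliberately.
- Kinetics: the single-exponential current fit starts after the 2-ms
  capacitive margin; the double-exponential fluorescence fit starts at pulse
  onset, because fluorescence carries no capacitive artifact and a delayed
  window attenuates the fitted fast amplitude by e^−margin/τ_f, corrupting
  the amplitude split.  Components are relabeled after convergence so
  τ_fast < τ_slow; fits with τ_slow/τ_fast < 2 are flagged poorly separated,
  vanishing amplitudes flagged degenerate.  Kinetics are fitted over
  −10…+40 mV, where the rises are large; the range is configurable.
- Relative amplitudes: each cell's leak-corrected +40 mV peak divided by the
  same-day control mean, which removes day-to-day expression variability and
  makes the control grand mean exactly 1 on a single day.

## Imaging pipeline

Synthetic images place non-overlapping circular cells (radius 15–30 px on a
512×512 canvas) whose membrane ring has a radial Gaussian profile of 3 px
nominal width; both channels share geometry, with the blue channel equal to
`ratio_true` times the red above a common flat background.  Interiors carry a
faint haze with the same ratio.

Segmentation is a marker-controlled watershed from per-cell interior seeds
plus background seeds.  The default elevation surface is the summed-channel
intensity itself: in a midplane image the stained membrane is the brightest
structure, so the watershed lines settle on the membrane-ring crest (label
areas within ~2% of the true disks; membrane-band Jaccard ~0.89 against the
generator ring).  A Sobel-gradient elevation is available as an option, but
for ring morphology its surface has ridges on both flanks of the ring and a
basin at the crest, which parks the watershed line about half a ring-width
off the membrane (Jaccard ~0.35) — appropriate only when boundaries are
intensity edges rather than bright ridges.

The membrane band takes, per label, its pixels within w/2 of the complement
plus background pixels within w/2 of the label measured to the half-pixel
label contour (default w = 3 px; both inner and outer rings, pixels interior
to another label never claimed).  Background is the median over pixels
outside a 2-px guard band around cells.  The excitation ratio is computed
pixelwise as (blue − bg_blue)/(red − bg_red) over membrane pixels whose red
signal exceeds 5% of the membrane median (excluded pixels are counted), and
summarized as the per-image mean and a fixed-bin histogram.  An
area/eccentricity morphology filter is deliberately not applied by default;
"normal morphology" selection is an acquisition-time judgment.

## Statistics

One-way fixed-effects ANOVA gates all-pairs Tukey HSD tests (Tukey–Kramer
for unequal n); pairwise p-values are always reported but flagged
not-interpreted when the ANOVA p ≥ α (default α = 0.05).  Degenerate inputs:
zero between- and within-group variance returns F = 0, p = 1; zero
within-group variance with distinct means returns F = ∞, p = 0.  p-values
below 1e−12 are displayed as "<1e-12".

## What the generators do and do not emulate

The generators reproduce the statistical structure the analysis relies on:
protocol timing, steady-state voltage dependence, exponential rise shapes,
leak, bleaching, detector noise, between-cell spread matched to group SEMs,
ring-cell geometry with a known channel ratio.  They do not emulate
inactivation, capacitive transients (available but off by default),
non-Gaussian artifacts (line noise, drift, endocytosed dye), irregular cell
shapes, overlapping cells, or spatially varying backgrounds.  Passing the
closed-loop suite therefore demonstrates the correctness and calibration of
the estimators under the stated model, not robustness to every artifact of
real recordings.

## Problem sizes

The closed-loop runs use the reference study's group sizes directly: 10–12
cells per VCF cohort (19 sweeps each, 5 kHz), 9 samples per probe group, and
20 image pairs per imaging condition with 30–40 cells each.  The full
acceptance run completes in about 10 s on one CPU; the test suite in about
half a minute.
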