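# Methods

This note documents the models and numerical choices behind `imugait`: what
the two event detectors compute, what the synthetic gait generator does and
does not emulate, and where the design was genuinely open.

## Gait model and event schedule

Walking is modelled as an alternating renewal process. Within each bout,
step times (interval from one foot's initial contact, IC, to the other
foot's IC) are independent truncated-normal draws: mean = stride_mean/2
(± half the step-asymmetry offset per side), SD = stride_SD/√2 so that
stride times — sums of two consecutive steps — have the preset SD;
truncation at ±3 SD, hard floor 0.2 s. Final contacts (FC) sit at a
per-cycle stance fraction of the stride after each IC, drawn from
N(mean, SD) and clipped to (0.55, 0.70). Consequences worth knowing:

* consecutive strides share a step, so stride times are MA(1)-correlated and
  the standard error of a stride mean carries a √2 factor over the iid
  formula;
* the ±3 SD truncation shrinks the realised stride SD by the truncated-normal
  factor (~1.3%);
* no stride-to-stride autocorrelation beyond the shared step, and no
  freezing-of-gait or turning dynamics, are modelled.

Cohort presets (within-subject timing plus between-subject spreads sampled
per subject in the pipeline) are anchored to published per-cohort summary
tables for young adults (stride 1.096 s), older adults (1.162 s) and
Parkinson's disease (1.168 s), including the across-subject SDs of those
tables. Subject-level stride means are floored at 1.0 s: self-selected
walking essentially never goes faster, and the event detectors' fixed search
windows (below) are only geometrically valid above roughly that cadence.
Waveform amplitudes (mid-swing ~150–250 deg/s, notch depths 90–180 deg/s,
lumbar oscillation ~1.2 m/s²) are typical literature magnitudes, **not**
values reported by any study; PD amplitudes are reduced to emulate short
shuffling steps.

Environment presets: treadmill = seven 60 s stages at 2–8 km/h with stride
time scaled by (speed/4.5 km/h)^−0.5 (an acknowledged heuristic, exposed as a
parameter); indoor = four 12 s walks with the speed condition cycling
normal/slow/fast/normal (stride scales 1.0/1.15/0.95), separated by 2 s
event-free gaps; outdoor = two 45 s walks. A single-bout preset supports
recovery experiments.

## Waveform synthesis and why it is shaped that way

The synthesis problem is inverse to detection: produce signals such that each
chain's extrema fall on the scripted events in the noise-free limit.

**Lumbar (L5) vertical acceleration.** The lumbar chain (integrate, then
differentiate twice with a scale-10 first-derivative-of-Gaussian CWT) is,
analytically, a heavy Gaussian smoother: at 100 Hz its effective kernel has
σ ≈ 70 ms per stage, which attenuates anything above ~3 Hz to near zero
after two stages. Two consequences drove the design:

1. an isolated symmetric transient at the IC puts the *second* stage's
   maxima on the transient's side lobes, never at the FC — so FC information
   cannot be carried by a sharp FC transient;
2. for a dominant oscillation with one period per step and a trough locked
   to each IC, the second stage's maxima fall exactly a quarter step-period
   after the preceding contralateral IC — which coincides with the scripted
   FC when the stance fraction is 0.625.

The vertical channel is therefore gravity + a per-step oscillation whose
piecewise-linear phase is locked to the ICs (trough at every IC), reinforced
by a Gaussian trough at each IC (width 0.10 × local step time) and a small
odd "rise" kernel at each FC. The deterministic part is made exactly
zero-mean so the channel mean equals g and the quasi-static tilt estimate is
exact. A configurable mounting-tilt rotation about the anterior axis and
white sensor noise complete the model. Because FC information travels
through oscillation phase, the lumbar algorithm's FC error grows with
|stance fraction − 0.625| — small for young adults (0.62), systematic for
the PD preset (0.60). This reproduces, by mechanism rather than by fiat, the
empirical finding that stance/swing agreement between the two algorithms is
worst in PD while stride/step agreement (IC-only) stays excellent.

**Shank sagittal angular velocity.** Per cycle: a positive Gaussian
mid-swing lobe (σ = 0.08 × swing time), a *narrow* negative notch at IC
(σ = 20 ms, 180 deg/s for YA) and a *wide* negative notch at FC (σ = 80 ms,
150 deg/s), plus linear drift and white noise. The width contrast is the
separation mechanism: in the wider-band approximation `a1` (0–13 Hz retained)
the sharp IC notch is the deepest negative peak of its search window, while
in the smoother `a2` (0–5 Hz) the narrow IC notch is attenuated to ~55% and
the wide FC notch barely at all, so the FC wins its window. The deeper FC
relative to IC in the low band mirrors real pre-swing (toe-off) morphology.
Kernel widths, depths and band edges were fixed once by a noise-free grid
scan across 60/100/128 Hz and not revisited.

The scripted mid-swing anchor is placed so that the following IC trails it by
max(0.30 s, 0.62 × swing), capped at swing − 0.07 s. A symmetric "midpoint
of swing" placement would put the next IC only ~0.21 s after mid-swing —
inside the fixed (tms + 0.25 s, tms + 2 s) IC window's dead zone — so it
cannot be used with the canonical window values.

## Detectors: numerical choices

* PyWavelets' `gaus1` CWT returns the *negative* of the smoothed derivative;
  the lumbar detector negates the coefficients so each stage is a plain
  smoothed d/dt (the convention the original MATLAB chains use). Verified
  against a sinusoid's closed-form extrema.
* CWT scale 10 is pinned to 100 Hz and scaled linearly with the sampling
  rate; a fixed scale in samples would change the analysed frequency band
  across the 60–128 Hz inputs.
* Filtering is zero-phase (forward–backward Butterworth), doubling the
  effective order; this avoids a systematic event delay that the agreement
  analysis would misattribute to the algorithms.
* Gravity is removed by mean subtraction before integration (prevents
  quadratic drift); integration is trapezoidal with initial value 0.
* Extrema are strict sign changes with a 0.25 s minimum separation and a
  relative prominence gate (≥ 25% of the largest candidate prominence) to
  suppress ripple in quiet segments; both gates are amplitude-invariant and
  shift-equivariant. Events within 4 wavelet scales of either end are
  discarded. At most one FC is kept between consecutive ICs (the strongest
  maximum), mirroring heel-strike/toe-off alternation.
* The 10-level Coiflet decomposition is capped at the feasible depth for the
  signal length (`pywt.dwt_max_level`; error below 3 levels). The deepest
  approximation is zeroed regardless of depth, which removes linear drift
  exactly (Coiflet vanishing moments), so the cap does not change results.
* "Global maximum" for the mid-swing anchor is read per cycle (relative
  height ≥ 0.2 × baseline maximum, separation ≥ 0.5 s); a literal single
  global maximum would anchor one cycle per recording.
* Most-negative-peak selection inside the search windows, ties broken toward
  the anchor; windows truncated at the recording boundaries and at the
  neighbouring anchors so no cycle can claim another cycle's events. Cycles
  missing either event are dropped and counted in diagnostics.
* The lumbar detector emits side-unassigned events. With both shank series
  available, each lumbar IC/FC takes the side of the nearest shank event of
  the same type, and events farther than 0.3 s from any shank event are
  discarded as spurious (the lumbar chain's "extra events" failure mode,
  typically in bout gaps). Lumbar-only mode alternates sides from the first
  event — a documented approximation that breaks if an event is missed.

## Temporal parameters and agreement

Cycles are consecutive same-side ICs with the unique FC strictly between
them; cycles with zero or multiple FCs, or spanning more than 2.5 s (bout
gaps), are dropped with diagnostics. Variability is the sample SD over all
cycles with sides pooled (mean of per-side SDs available as an option);
asymmetry is |left mean − right mean| (per-cycle |L−R| available as an
option). The step attributed to a cycle row is the contralateral foot's
step, and step asymmetry uses the stepping foot's label.

The ICC is the single-measure absolute-agreement form from the two-way ANOVA
decomposition — the estimate the field labels ICC(2,1) — with the F-based
confidence interval and p-value of McGraw & Wong. The two-way *random* and
*mixed* specifications share this point estimate; the CI follows the
absolute-agreement formulas. A zero-variance matrix raises rather than
reporting ICC = 1. Limits of agreement use the conventional 1.96 multiplier.
Categorical labels follow the printed bins, with gap values (e.g. 0.905)
resolved downward. p-values are reported raw; no multiple-testing correction
is applied.

The full five-cell default study (16 + 31 + 25 + 20 + 36 subjects at 100 Hz)
runs in a few seconds; validation experiments use 60 s single-bout subjects
(~54 strides per side), 20 subjects per cohort for parameter recovery and 50
replicate cells for the agreement-pattern experiment — sizes chosen so the
Monte-Carlo error is well below the effects being measured.

## What passing tests do and do not show

The simulator produces exactly the signal structure each algorithm assumes,
with controllable violations (noise, drift, tilt, cadence, stance fraction).
Tests therefore establish that the *implementations* of the chains are
correct and that the agreement analysis behaves as theory predicts
(mean parameters agree best; FC-dependent parameters degrade; event jitter
monotonically destroys variability agreement). They do **not** establish
accuracy on real recordings: real waveforms contain inter-subject morphology
differences, soft-tissue artefacts, turning and postural transitions that
the generator deliberately omits. Known limitations: the lumbar chain's
smoothing compresses per-cycle timing variability by ~5–8% (a property of
strictly filtered detectors, visible here because ground truth is known);
the shank algorithm structurally misses the first IC of every bout (no
preceding mid-swing anchor); resampling is linear interpolation without an
anti-alias filter; and fast cadences (stride ≲ 0.95 s) fall outside the
canonical search-window geometry — on the treadmill ramp's fast stages both
algorithms degrade, which is realistic but means treadmill agreement numbers
are dominated by those stages.
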