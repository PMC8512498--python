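# imugait

Wearable-IMU gait event detection and inter-algorithm agreement analysis.

Body-worn inertial measurement units (IMUs) are a standard way to quantify
gait outside the motion-capture lab: a sensor on the lower back (fifth lumbar
vertebra, L5) or on each shank is enough to detect the two events that
segment every gait cycle — initial contact (IC, heel strike) and final
contact (FC, toe off) — and from them the temporal gait parameters clinicians
use (stride, stance, swing and step times, their variability and left–right
asymmetry). Different sensor locations need different algorithms, and the
two most common ones do **not** necessarily agree, especially in older adults
and people with Parkinson's disease (PD) or outside the lab. This package is
for movement-analysis researchers who want to quantify that agreement, and to
study *why* it degrades, on fully controlled synthetic data with known
ground-truth events.

## What is implemented

**Algorithm A1 (lower back).** The tri-axial L5 acceleration is rotated into
a horizontal–vertical frame from the quasi-static gravity estimate
(Moe-Nilssen-style tilt correction), low-pass filtered (4th-order
Butterworth, 20 Hz, zero-phase), numerically integrated (cumulative
trapezoid), then differentiated with a first-order Gaussian (`gaus1`)
continuous wavelet transform at scale 10 (pinned to 100 Hz, scaled linearly
with the sampling rate). ICs are the local minima of the CWT output
`W[∫a_v]`; a second CWT differentiation gives FCs at the local maxima of
`W[W[∫a_v]]`. The detector sees both feet and emits side-unassigned events.

**Algorithm A2 (shanks).** Each shank's sagittal-plane angular velocity is
decomposed with 5th-order Coiflets (`coif5`, up to 10 levels); the deepest
approximation (drift — exactly removed thanks to the Coiflet vanishing
moments) and the finest details (sensor noise) are suppressed, leaving
band-limited approximations `a1` (wider band, keeps the sharp IC notch) and
`a2` (smoother, favours the broad FC notch). Per cycle, the mid-swing time
`tms` is a positive peak of the denoised baseline; then

```
IC = most negative peak of a1 in (tms + 0.25 s, tms + 2 s)
FC = most negative peak of a2 in (tms − 2 s,  tms − 0.05 s)
```

with windows truncated at the neighbouring `tms`.

**Temporal parameters.** With per-side IC/FC sequences, for cycle *k*:
`stride = IC(k+1) − IC(k)`, `stance = FC(k) − IC(k)`,
`swing = IC(k+1) − FC(k)` (so stride ≡ stance + swing exactly), and
`step = IC − preceding contralateral IC`. Per subject the package reports
mean, variability (SD over cycles, sides pooled) and asymmetry
(|left mean − right mean|) of each parameter.

**Agreement statistics.** Across the subjects of a cohort/environment cell,
per parameter and statistic: Pearson r, Spearman ρ, the single-measure
absolute-agreement intraclass correlation ICC(2,1) from the two-way ANOVA
decomposition

```
ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n),   k = 2
```

with McGraw–Wong F-based 95% CI and p-value; a categorical label (≤0.30
none, 0.31–0.50 fair, 0.51–0.70 moderate, 0.71–0.90 substantial, ≥0.91 very
good); the absolute difference of means AD = |A1 − A2|; Bland–Altman mean
difference and 1.96-SD limits of agreement; and an OLS regression of one
method on the other.

**Synthetic gait simulator.** Ground-truth bilateral IC/FC schedules with
cohort presets (young adults YA, older adults OA, PD; stride timing anchored
to published per-cohort summary statistics) and environment presets
(treadmill 2–8 km/h ramp, repeated indoor walks, outdoor walks), plus
matching lumbar and shank waveforms designed so that, noise-free, each
detection chain's extrema fall on the scripted events. Sensor noise,
gyroscope drift and mounting tilt are configurable.

## Worked example

```python
from imugait import (
    COHORT_PRESETS, single_bout_preset, make_gait_script,
    synthesize_lumbar_accel, synthesize_shank_gyro,
    detect_events_lumbar_recording, detect_events_shank_recording,
    assign_sides_lumbar, summarize_events, match_events,
)

# one simulated young adult: 60 s of walking recorded at 100 Hz
script = make_gait_script(COHORT_PRESETS["YA"], single_bout_preset(60.0), seed=42)
lumbar = synthesize_lumbar_accel(script, fs=100.0, noise_sd=0.15, seed=1, tilt_deg=5.0)
shanks = {s: synthesize_shank_gyro(script, s, fs=100.0, noise_sd=5.0,
                                   drift_rate=0.1, seed=2) for s in "LR"}

ev_shank = {s: detect_events_shank_recording(r) for s, r in shanks.items()}
lum_L, lum_R = assign_sides_lumbar(detect_events_lumbar_recording(lumbar),
                                   ev_shank["L"], ev_shank["R"])

m = match_events(ev_shank["L"].ic_times, script.ic_times("L"), tolerance=0.05)
print(f"shank ICs recovered: {m.n_matched}/{m.n_reference} "
      f"(median |error| {1000*m.median_abs_error:.1f} ms)")
for name, (L, R) in {"lumbar": (lum_L, lum_R),
                     "shank": (ev_shank["L"], ev_shank["R"])}.items():
    s = summarize_events(L, R)
    print(f"{name:6s} stride {s.value('stride','mean'):.3f} s  "
          f"stance {s.value('stance','mean'):.3f} s  "
          f"swing {s.value('swing','mean'):.3f} s  "
          f"step {s.value('step','mean'):.3f} s  ({s.n_cycles} cycles)")
```

prints

```
shank ICs recovered: 54/55 (median |error| 2.3 ms)
lumbar stride 1.093 s  stance 0.681 s  swing 0.412 s  step 0.546 s  (105 cycles)
shank  stride 1.093 s  stance 0.670 s  swing 0.423 s  step 0.547 s  (105 cycles)
```

Both algorithms recover the scripted ~1.09 s stride to the millisecond; the
FC-dependent parameters (stance, swing) differ by ~10 ms between methods —
exactly the pattern that makes stance/swing agreement the weak point of
between-algorithm comparisons. The one unrecovered shank IC is the first
contact of the bout, which has no preceding mid-swing anchor.

A whole multi-cell study (cohorts × environments, with per-cell agreement
tables and a run manifest) is one call or one command:

```bash
imugait simulate-study --seed 1 --out results/study/
```

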