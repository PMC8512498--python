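"""Synthetic gait-event schedules and matching lumbar/shank IMU waveforms.

The generator produces, for one simulated subject, a bilateral ground-truth
schedule of initial contacts (IC, heel strike) and final contacts (FC,
toe off) -- a :class:`GaitScript` -- and then renders IMU waveforms with the
structure the two detectors assume:

* lower-back (L5) vertical acceleration with one dominant transient per step,
* shank sagittal angular velocity with a large positive mid-swing lobe per
  cycle and negative notches at IC and FC.

Waveforms are built so that, in the noise-free limit, the detection chains'
extrema fall on the scripted event times.  The lumbar channel is a dominant
per-step oscillation whose phase is locked to the ICs (trough exactly at
each IC; the chain's twice-differentiated maximum then falls a quarter
step-period later, i.e. at the FC for stance fractions near 0.62),
reinforced by a Gaussian trough at each IC and a small odd rise kernel at
each FC.  The shank channel uses a sharp deep notch at IC and a wider,
similarly deep notch at FC: the width contrast is what the detector's two
band-limited approximations separate.

Cohort presets (young adults YA, older adults OA, Parkinson's disease PD)
carry the stride-timing statistics the analysis assumes; environment presets
(treadmill speed ramp, repeated indoor walks, outdoor walks) define the bout
structure.  Timing values are anchored to published per-cohort summary tables;
waveform amplitudes are typical literature magnitudes, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import STANDARD_GRAVITY, AxisConvention, IMURecording, Placement

# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortPreset:
    """Timing statistics and waveform morphology for one simulated cohort.

    ``*_between_sd`` fields are between-subject spreads used when sampling a
    subject-specific preset from the cohort; the plain fields are the
    within-subject (per-cycle) parameters.
    """

    name: str
    stride_mean: float  # s
    stride_sd: float  # s, per-cycle (within subject)
    stance_fraction_mean: float = 0.62
    stance_fraction_sd: float = 0.015
    step_asymmetry_offset: float = 0.0  # s, added to left step time
    midswing_amplitude: float = 250.0  # deg/s
    ic_notch_depth: float = 180.0  # deg/s
    fc_notch_depth: float = 150.0  # deg/s
    tremor_amplitude: float = 0.0  # deg/s, optional rest-tremor ripple
    stride_mean_between_sd: float = 0.0
    stride_sd_between_sd: float = 0.0
    stance_fraction_between_sd: float = 0.01
    asymmetry_between_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.stride_mean <= 0:
            raise ValueError("stride_mean must be positive")
        if self.stride_sd < 0:
            raise ValueError("stride_sd must be non-negative")
        for a in (self.midswing_amplitude, self.ic_notch_depth, self.fc_notch_depth,
                  self.tremor_amplitude):
            if a < 0:
                raise ValueError("waveform amplitudes must be non-negative")

    def sample_subject(self, rng: np.random.Generator) -> "CohortPreset":
        """Draw a subject-specific preset around the cohort-level values."""
        # self-selected walking essentially never drops below ~1.0 s stride;
        # the floor keeps fast draws inside the detectors' validity region
        stride_mean = max(1.0, rng.normal(self.stride_mean, self.stride_mean_between_sd))
        stride_sd = float(np.clip(rng.normal(self.stride_sd, self.stride_sd_between_sd),
                                  0.005, 0.25))
        sf = float(np.clip(rng.normal(self.stance_fraction_mean,
                                      self.stance_fraction_between_sd), 0.58, 0.66))
        asym = rng.normal(self.step_asymmetry_offset, self.asymmetry_between_sd)
        return replace(
            self,
            stride_mean=float(stride_mean),
            stride_sd=stride_sd,
            stance_fraction_mean=sf,
            step_asymmetry_offset=float(asym),
            stride_mean_between_sd=0.0,
            stride_sd_between_sd=0.0,
            stance_fraction_between_sd=0.0,
            asymmetry_between_sd=0.0,
        )


# Cohort timing values anchored to the published per-cohort indoor summary
# tables (lumbar-algorithm column): stride means 1.096 / 1.162 / 1.168 s and
# their across-subject SDs; per-cycle stride SDs from the variability rows.
# Mid-swing amplitudes are typical shank angular-velocity magnitudes from the
# gait literature (not reported in the study); PD amplitude is reduced to
# emulate short shuffling steps.
COHORT_PRESETS = {
    "YA": CohortPreset(
        name="YA", stride_mean=1.096, stride_sd=0.040,
        step_asymmetry_offset=0.011,
        midswing_amplitude=250.0,
        stride_mean_between_sd=0.138, stride_sd_between_sd=0.015,
        asymmetry_between_sd=0.008,
    ),
    "OA": CohortPreset(
        name="OA", stride_mean=1.162, stride_sd=0.086,
        stance_fraction_mean=0.61,
        step_asymmetry_offset=0.000,
        midswing_amplitude=200.0, ic_notch_depth=145.0, fc_notch_depth=120.0,
        stride_mean_between_sd=0.077, stride_sd_between_sd=0.025,
        asymmetry_between_sd=0.004,
    ),
    "PD": CohortPreset(
        name="PD", stride_mean=1.168, stride_sd=0.083,
        stance_fraction_mean=0.60,
        step_asymmetry_offset=0.002,
        midswing_amplitude=150.0, ic_notch_depth=110.0, fc_notch_depth=90.0,
        stride_mean_between_sd=0.096, stride_sd_between_sd=0.030,
        stance_fraction_between_sd=0.015,
        asymmetry_between_sd=0.005,
    ),
}


@dataclass(frozen=True)
class Bout:
    start: float
    duration: float
    stride_scale: float = 1.0

    @property
    def stop(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class EnvironmentPreset:
    """Bout structure and speed profile of one walking protocol."""

    name: str
    bouts: tuple[Bout, ...]

    def __post_init__(self) -> None:
        if not self.bouts or any(b.duration <= 0 for b in self.bouts):
            raise ValueError("environment must contain bouts of positive duration")

    @property
    def total_duration(self) -> float:
        return self.bouts[-1].stop


def treadmill_preset(stage_duration: float = 60.0,
                     speeds_kmh: Sequence[float] = (2, 3, 4, 5, 6, 7, 8),
                     reference_speed_kmh: float = 4.5) -> EnvironmentPreset:
    """Treadmill ramp: speed incremented every minute from 2-8 km/h.

    Cadence scales with belt speed via stride_time ~ speed^-0.5 (an
    acknowledged heuristic); the cohort stride_mean applies at the reference
    self-selected speed.
    """
    if len(speeds_kmh) != 7:
        raise ValueError("treadmill ramp has 7 one-minute stages (2-8 km/h)")
    bouts, t = [], 0.0
    for v in speeds_kmh:
        bouts.append(Bout(t, stage_duration, (v / reference_speed_kmh) ** -0.5))
        t += stage_duration
    return EnvironmentPreset("treadmill", tuple(bouts))


def indoor_preset(walk_duration: float = 12.0, gap: float = 2.0) -> EnvironmentPreset:
    """Four 10-20 m indoor walks at normal, slow, fast, normal speed."""
    scales = (1.0, 1.15, 0.95, 1.0)
    bouts, t = [], 0.0
    for s in scales:
        bouts.append(Bout(t, walk_duration, s))
        t += walk_duration + gap
    return EnvironmentPreset("indoor", tuple(bouts))


def outdoor_preset(walk_duration: float = 45.0, gap: float = 4.0) -> EnvironmentPreset:
    """Two 40-80 m outdoor walks at a self-selected speed."""
    return EnvironmentPreset(
        "outdoor", (Bout(0.0, walk_duration), Bout(walk_duration + gap, walk_duration))
    )


def single_bout_preset(duration: float = 60.0) -> EnvironmentPreset:
    """One uninterrupted walk; convenient for recovery experiments."""
    return EnvironmentPreset("single", (Bout(0.0, duration),))


ENVIRONMENT_PRESETS = {
    "treadmill": treadmill_preset,
    "indoor": indoor_preset,
    "outdoor": outdoor_preset,
    "single": single_bout_preset,
}


# ---------------------------------------------------------------------------
# gait script
# ---------------------------------------------------------------------------


@dataclass
class GaitScript:
    """Ground-truth bilateral IC/FC schedule; the oracle for detector tests."""

    ic_left: np.ndarray
    fc_left: np.ndarray
    ic_right: np.ndarray
    fc_right: np.ndarray
    bouts: tuple[Bout, ...]
    params: dict = field(default_factory=dict)

    def ic_times(self, side: str) -> np.ndarray:
        return self.ic_left if side == "L" else self.ic_right

    def fc_times(self, side: str) -> np.ndarray:
        return self.fc_left if side == "L" else self.fc_right

    def all_ic_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.ic_left, self.ic_right]))

    def all_fc_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.fc_left, self.fc_right]))

    @property
    def end_time(self) -> float:
        events = [a for a in (self.ic_left, self.ic_right) if a.size]
        return max(float(a[-1]) for a in events) if events else 0.0

    @property
    def n_events(self) -> int:
        return sum(a.size for a in (self.ic_left, self.fc_left, self.ic_right, self.fc_right))

    def stride_times(self, side: str) -> np.ndarray:
        ics = self.ic_times(side)
        strides = np.diff(ics)
        # strides that bridge a bout gap are not gait cycles
        return strides[strides < 2.5]

    def midswing_times(self, side: str) -> np.ndarray:
        """Scripted mid-swing anchor per complete cycle.

        Placed so the following IC trails the mid-swing by
        max(0.30 s, 0.62 * swing), capped at swing - 0.10 s, keeping both the
        IC and the FC inside the shank algorithm's fixed search windows.
        """
        ics, fcs = self.ic_times(side), self.fc_times(side)
        out = []
        for k in range(fcs.size):
            nxt = ics[ics > fcs[k]]
            if not nxt.size or nxt[0] - fcs[k] > 2.5:
                continue
            swing = nxt[0] - fcs[k]
            lead = _ic_lead(swing)
            out.append(nxt[0] - lead)
        return np.asarray(out)


def _ic_lead(swing: float) -> float:
    if swing < 0.2:
        return swing / 2.0
    return min(max(0.62 * swing, 0.30), swing - 0.07)


def _rng_from_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required: synthetic data must be reproducible")
    return np.random.default_rng(seed)


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                    floor: float = 0.2) -> float:
    """Normal draw truncated at +-3 SD with a hard floor."""
    if sd == 0:
        return max(mean, floor)
    x = rng.normal(mean, sd)
    while abs(x - mean) > 3 * sd:
        x = rng.normal(mean, sd)
    return max(x, floor)


def make_gait_script(cohort: CohortPreset, environment: EnvironmentPreset,
                     seed) -> GaitScript:
    """Draw a bilateral IC/FC schedule for one subject.

    Step times are independent truncated-normal draws (per-step SD =
    stride SD / sqrt(2), so that stride times -- sums of two consecutive
    steps -- recover the preset stride SD).  Left and right ICs alternate
    within each bout; the asymmetry offset is split +-offset/2 between the
    sides so the stride mean is unchanged.  FCs sit at a per-cycle stance
    fraction of the stride after each IC.  Bout gaps contain no events.
    """
    rng = _rng_from_seed(seed)
    step_sd = cohort.stride_sd / np.sqrt(2.0)
    ics = {"L": [], "R": []}
    for bout in environment.bouts:
        step_mean = {
            "L": cohort.stride_mean * bout.stride_scale / 2.0 + cohort.step_asymmetry_offset / 2.0,
            "R": cohort.stride_mean * bout.stride_scale / 2.0 - cohort.step_asymmetry_offset / 2.0,
        }
        side = "L"
        t = bout.start + 0.4
        ics[side].append(t)
        while True:
            side = "R" if side == "L" else "L"
            t = t + _draw_truncnorm(rng, step_mean[side], step_sd)
            if t > bout.stop - 0.4:
                break
            ics[side].append(t)

    fcs = {"L": [], "R": []}
    for side in ("L", "R"):
        arr = np.asarray(ics[side])
        for k in range(arr.size - 1):
            stride = arr[k + 1] - arr[k]
            if stride > 2.5:  # bridges a bout gap
                continue
            sf = float(np.clip(rng.normal(cohort.stance_fraction_mean,
                                          cohort.stance_fraction_sd), 0.55, 0.70))
            fcs[side].append(arr[k] + sf * stride)

    return GaitScript(
        ic_left=np.asarray(ics["L"]),
        fc_left=np.asarray(fcs["L"]),
        ic_right=np.asarray(ics["R"]),
        fc_right=np.asarray(fcs["R"]),
        bouts=environment.bouts,
        params={
            "cohort": cohort.name,
            "environment": environment.name,
            "stride_mean": cohort.stride_mean,
            "stride_sd": cohort.stride_sd,
            "stance_fraction_mean": cohort.stance_fraction_mean,
            "step_asymmetry_offset": cohort.step_asymmetry_offset,
            "midswing_amplitude": cohort.midswing_amplitude,
            "ic_notch_depth": cohort.ic_notch_depth,
            "fc_notch_depth": cohort.fc_notch_depth,
            "tremor_amplitude": cohort.tremor_amplitude,
            "seed": repr(seed),
        },
    )


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


def _add_kernel(signal: np.ndarray, fs: float, center: float, width: float,
                shape) -> None:
    """Add ``shape(u)`` with u=(t-center)/width on a local +-6 width window."""
    n = signal.size
    i0 = max(0, int(np.floor((center - 6 * width) * fs)))
    i1 = min(n, int(np.ceil((center + 6 * width) * fs)) + 1)
    if i0 >= i1:
        return
    u = (np.arange(i0, i1) / fs - center) / width
    signal[i0:i1] += shape(u)


def _odd_dgauss(u: np.ndarray) -> np.ndarray:
    return u * np.exp(-0.5 * u**2)


def _gauss(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u**2)


def _rotation_about_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _step_phase_oscillation(
    script: GaitScript, t: np.ndarray, fs: float, amplitude: float,
    ramp: float = 0.3,
) -> np.ndarray:
    """Dominant per-step pelvic oscillation, phase-locked to the ICs.

    Within each bout the instantaneous phase advances by one full cycle per
    step (piecewise-linear between IC knots, linearly extrapolated to the bout
    edges), and the waveform is ``-amplitude * cos(phase)``: a trough exactly
    at every IC of either side.  A raised-cosine envelope tapers each bout in
    and out so gaps stay event- and oscillation-free.
    """
    out = np.zeros_like(t)
    all_ics = script.all_ic_times()
    for bout in script.bouts:
        ics = all_ics[(all_ics >= bout.start) & (all_ics <= bout.stop)]
        if ics.size < 2:
            continue
        step0 = ics[1] - ics[0]
        step1 = ics[-1] - ics[-2]
        knots_t = np.concatenate([[bout.start - 1e-9], ics, [bout.stop + 1e-9]])
        knots_p = np.concatenate(
            [
                [-2 * np.pi * (ics[0] - bout.start) / step0],
                2 * np.pi * np.arange(ics.size, dtype=float),
                [2 * np.pi * (ics.size - 1 + (bout.stop - ics[-1]) / step1)],
            ]
        )
        i0 = max(0, int(np.ceil(bout.start * fs)))
        i1 = min(t.size, int(np.floor(bout.stop * fs)) + 1)
        if i0 >= i1:
            continue
        phase = np.interp(t[i0:i1], knots_t, knots_p)
        env = np.ones(i1 - i0)
        m = min(int(ramp * fs), (i1 - i0) // 2)
        if m > 0:
            r = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
            env[:m] *= r
            env[-m:] *= r[::-1]
        out[i0:i1] += -amplitude * np.cos(phase) * env
    return out


def synthesize_lumbar_accel(
    script: GaitScript,
    fs: float,
    noise_sd: float = 0.15,
    seed=None,
    tilt_deg: float = 0.0,
    osc_amplitude: float = 1.2,
    ic_amplitude: float = 0.8,
    fc_amplitude: float = 0.4,
    subject_id: str = "",
    pad: float = 0.8,
) -> IMURecording:
    """Render the L5 recording implied by a gait script.

    The vertical channel is gravity plus one dominant oscillation per step
    (trough locked to each IC of either side), reinforced by a Gaussian trough
    at each IC (width scaled to the local step time) and a small odd
    rise kernel at each FC.  The deterministic part is made exactly zero-mean,
    so the channel mean is g.  A fixed sensor-tilt rotation about the anterior
    axis is applied to all three channels so that tilt correction is
    exercised; white sensor noise is added after the rotation.
    """
    if fs < 30:
        raise ValueError("lumbar synthesis requires fs >= 30 Hz")
    if script.n_events == 0:
        raise ValueError("gait script contains no events")
    rng = _rng_from_seed(seed if seed is not None else 0) if noise_sd > 0 else None

    n = int(round((script.end_time + pad) * fs)) + 1
    t = np.arange(n) / fs
    vert = _step_phase_oscillation(script, t, fs, osc_amplitude)

    all_ics = script.all_ic_times()
    for k, tic in enumerate(all_ics):
        nxt = all_ics[k + 1] - tic if k + 1 < all_ics.size else np.inf
        prv = tic - all_ics[k - 1] if k > 0 else np.inf
        step = min(nxt, prv)
        if not np.isfinite(step) or step > 1.5:
            step = 0.55
        w = float(np.clip(0.10 * step, 0.03, 0.12))
        _add_kernel(vert, fs, tic, w, lambda u: -ic_amplitude * _gauss(u))
    for tfc in script.all_fc_times():
        _add_kernel(vert, fs, tfc, 0.030, lambda u: fc_amplitude * _odd_dgauss(u))
    vert -= vert.mean()

    ap = np.zeros(n)
    ml = np.zeros(n)
    if noise_sd > 0:
        # horizontal channels: small-amplitude low-passed (correlated) noise
        from scipy.ndimage import gaussian_filter1d

        ap += gaussian_filter1d(rng.normal(0, 2.0 * noise_sd, n), 0.1 * fs)
        ml += gaussian_filter1d(rng.normal(0, 2.0 * noise_sd, n), 0.1 * fs)
        ap -= ap.mean()
        ml -= ml.mean()

    accel = np.column_stack([ap, ml, vert + STANDARD_GRAVITY])
    if tilt_deg != 0.0:
        accel = accel @ _rotation_about_x(tilt_deg).T
    if noise_sd > 0:
        accel = accel + rng.normal(0, noise_sd, accel.shape)

    gyro = np.zeros((n, 3))
    if noise_sd > 0:
        gyro = rng.normal(0, 1.0, (n, 3))

    return IMURecording(
        placement=Placement.L5,
        fs=fs,
        t=t,
        accel=accel,
        gyro=gyro,
        axis_convention=AxisConvention(),
        subject_id=subject_id,
        metadata={"synthetic": True, "tilt_deg": tilt_deg, "noise_sd": noise_sd,
                  **script.params},
    )


def synthesize_shank_gyro(
    script: GaitScript,
    side: str,
    fs: float,
    noise_sd: float = 5.0,
    drift_rate: float = 0.0,
    seed=None,
    midswing_amplitude: float | None = None,
    ic_notch_depth: float | None = None,
    fc_notch_depth: float | None = None,
    tremor_amplitude: float | None = None,
    subject_id: str = "",
    pad: float = 0.8,
) -> IMURecording:
    """Render one shank's recording implied by a gait script.

    The sagittal gyro channel carries, per complete cycle, a large positive
    Gaussian mid-swing lobe centred on the scripted mid-swing time, plus
    negative notches at each scripted IC (narrow, deep) and FC (wider,
    shallower).  The width contrast is what lets the shank algorithm's two
    band-limited approximations separate them.  Linear gyroscope drift and
    white noise are added on top.
    """
    if fs < 30:
        raise ValueError("shank synthesis requires fs >= 30 Hz")
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    ics = script.ic_times(side)
    if ics.size == 0:
        raise ValueError(f"side {side!r} absent from script")
    amp = script.params.get("midswing_amplitude", 250.0) if midswing_amplitude is None else midswing_amplitude
    d_ic = script.params.get("ic_notch_depth", 180.0) if ic_notch_depth is None else ic_notch_depth
    d_fc = script.params.get("fc_notch_depth", 150.0) if fc_notch_depth is None else fc_notch_depth
    tremor = script.params.get("tremor_amplitude", 0.0) if tremor_amplitude is None else tremor_amplitude

    rng = _rng_from_seed(seed if seed is not None else 0) if noise_sd > 0 else None
    n = int(round((script.end_time + pad) * fs)) + 1
    t = np.arange(n) / fs
    sag = np.zeros(n)

    fcs = script.fc_times(side)
    tms = script.midswing_times(side)
    for k in range(fcs.size):
        nxt = ics[ics > fcs[k]]
        if not nxt.size or nxt[0] - fcs[k] > 2.5:
            continue
        swing = nxt[0] - fcs[k]
        w_ms = max(0.03, 0.08 * swing)
        _add_kernel(sag, fs, tms[k] if k < tms.size else fcs[k] + swing / 2,
                    w_ms, lambda u: amp * _gauss(u))
    for tic in ics:
        _add_kernel(sag, fs, tic, 0.020, lambda u: -d_ic * _gauss(u))
    for tfc in fcs:
        _add_kernel(sag, fs, tfc, 0.080, lambda u: -d_fc * _gauss(u))

    if tremor > 0:
        sag = sag + tremor * np.sin(2 * np.pi * 5.0 * t)
    sag = sag + drift_rate * t
    gyro = np.zeros((n, 3))
    gyro[:, 1] = sag
    accel = np.zeros((n, 3))
    accel[:, 2] = STANDARD_GRAVITY
    if noise_sd > 0:
        gyro = gyro + rng.normal(0, noise_sd, gyro.shape)
        accel = accel + rng.normal(0, 0.05, accel.shape)

    return IMURecording(
        placement=Placement.SHANK_LEFT if side == "L" else Placement.SHANK_RIGHT,
        fs=fs,
        t=t,
        accel=accel,
        gyro=gyro,
        axis_convention=AxisConvention(),
        subject_id=subject_id,
        metadata={"synthetic": True, "side": side, "noise_sd": noise_sd,
                  "drift_rate": drift_rate, **script.params},
    )
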