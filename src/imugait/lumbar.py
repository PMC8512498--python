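"""Lower-back (L5) gait event detection from vertical acceleration.

The chain: tilt-correct the tri-axial signal to a horizontal-vertical frame
from the quasi-static gravity estimate, low-pass filter (4th-order
Butterworth, 20 Hz, zero-phase), numerically integrate (cumulative
trapezoid), then differentiate with a first-order-Gaussian (gaus1) continuous
wavelet transform at scale 10 (pinned to 100 Hz and scaled linearly with the
sampling rate).  ICs are local minima of the CWT output; a second gaus1
differentiation yields FCs at local maxima.  The detector sees both feet and
therefore emits side-unassigned events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt, find_peaks

from .events import EventSeries
from .io_formats import STANDARD_GRAVITY, IMURecording, Placement


@dataclass(frozen=True)
class LumbarDetectorConfig:
    lowpass_cutoff: float = 20.0  # Hz
    filter_order: int = 4
    wavelet: str = "gaus1"
    cwt_scale_ref: float = 10.0  # dimensionless scale at the 100 Hz reference rate
    min_event_separation: float = 0.25  # s
    gravity_removal: bool = True
    #: relative prominence gate: minima/maxima whose prominence is below this
    #: fraction of the largest candidate prominence are treated as ripple.
    min_prominence_frac: float = 0.25
    #: events within this many wavelet scales of either end are discarded
    boundary_scales: float = 4.0

    def validate(self, fs: float) -> None:
        if not 0 < self.lowpass_cutoff < fs / 2:
            raise ValueError(
                f"lowpass cutoff {self.lowpass_cutoff} Hz must lie in (0, fs/2) "
                f"for fs={fs} Hz"
            )
        if self.cwt_scale_ref <= 0:
            raise ValueError("cwt_scale_ref must be positive")


def tilt_correct_to_vertical(rec: IMURecording) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the accelerometer frame so gravity lies on the vertical axis.

    The rotation is computed from the mean acceleration direction (the
    quasi-static gravity estimate, a two-step trunk tilt correction in the
    Moe-Nilssen style) and applied per sample, so vector norms are preserved.

    Returns ``(vertical, horizontal)`` where vertical is the gravity-aligned
    channel (mean +g before any gravity subtraction) and horizontal is the
    (n, 2) remainder.
    """
    if rec.accel.shape[0] < 2 or rec.duration < 2.0:
        raise ValueError("tilt correction requires at least 2 s of data")
    mean_vec = rec.accel.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if not 0.5 * STANDARD_GRAVITY < norm < 1.5 * STANDARD_GRAVITY:
        raise ValueError(
            "mean acceleration magnitude outside (0.5 g, 1.5 g): sensor not "
            "quasi-static or wrong units"
        )
    g_dir = mean_vec / norm
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(g_dir, target)
    c = float(np.dot(g_dir, target))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    rotated = rec.accel @ rot.T
    return rotated[:, 2], rotated[:, :2]


def _cwt_gaus1_derivative(x: np.ndarray, scale: float) -> np.ndarray:
    """Smoothed differentiation via the gaus1 CWT.

    PyWavelets' gaus1 correlation returns the *negative* of the Gaussian-
    smoothed derivative (its mother wavelet is -x exp(-x^2) up to
    normalisation), so the coefficients are negated here to make this stage a
    plain smoothed d/dt, the convention the original MATLAB chain uses.
    """
    coefs, _ = pywt.cwt(x, [scale], "gaus1")
    return -coefs[0]


def detect_events_lumbar(
    vertical_accel: np.ndarray,
    fs: float,
    config: LumbarDetectorConfig | None = None,
) -> EventSeries:
    """Detect ICs and FCs from the L5 vertical acceleration channel.

    Returns a side-unassigned :class:`EventSeries`; between consecutive ICs at
    most one FC is kept (the strongest maximum of the twice-differentiated
    output), mirroring the alternation of heel strikes and toe offs.
    """
    config = config or LumbarDetectorConfig()
    config.validate(fs)
    x = np.asarray(vertical_accel, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long")

    if config.gravity_removal:
        x = x - x.mean()
    b, a = butter(config.filter_order, config.lowpass_cutoff, fs=fs)
    x = filtfilt(b, a, x)
    v = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)

    scale = config.cwt_scale_ref * fs / 100.0
    c1 = _cwt_gaus1_derivative(v, scale)

    dist = max(1, int(round(config.min_event_separation * fs)))
    ic_idx, ic_props = find_peaks(-c1, distance=dist, prominence=0.0)
    ic_idx = _prominence_gate(ic_idx, ic_props, config.min_prominence_frac)

    diagnostics = {"n_ic_candidates": int(ic_idx.size)}
    if ic_idx.size == 0:
        diagnostics["warning"] = "no IC minima found"
        return EventSeries(Placement.L5, "unassigned", np.array([]), np.array([]),
                           diagnostics)

    c2 = _cwt_gaus1_derivative(c1, scale)
    fc_idx, fc_props = find_peaks(c2, distance=dist, prominence=0.0)
    fc_idx = _prominence_gate(fc_idx, fc_props, config.min_prominence_frac)

    # keep at most one FC per IC-to-IC interval: the strongest maximum
    kept_fc = []
    for lo, hi in zip(ic_idx[:-1], ic_idx[1:]):
        inside = fc_idx[(fc_idx > lo) & (fc_idx < hi)]
        if inside.size:
            kept_fc.append(inside[np.argmax(c2[inside])])
    fc_idx = np.asarray(kept_fc, dtype=int)

    margin = int(round(config.boundary_scales * scale))
    n = x.size
    ic_idx = ic_idx[(ic_idx >= margin) & (ic_idx <= n - 1 - margin)]
    fc_idx = fc_idx[(fc_idx >= margin) & (fc_idx <= n - 1 - margin)]

    diagnostics["n_ic"] = int(ic_idx.size)
    diagnostics["n_fc"] = int(fc_idx.size)
    return EventSeries(
        Placement.L5, "unassigned", ic_idx / fs, fc_idx / fs, diagnostics
    )


def _prominence_gate(idx: np.ndarray, props: dict, frac: float) -> np.ndarray:
    if idx.size == 0 or frac <= 0:
        return idx
    prom = props["prominences"]
    return idx[prom >= frac * prom.max()]


def detect_events_lumbar_recording(
    rec: IMURecording, config: LumbarDetectorConfig | None = None
) -> EventSeries:
    """Convenience wrapper: tilt-correct a recording, then detect events."""
    vertical, _ = tilt_correct_to_vertical(rec)
    return detect_events_lumbar(vertical, rec.fs, config)
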