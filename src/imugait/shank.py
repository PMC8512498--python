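"""Shank gait event detection from sagittal angular velocity.

The chain: multi-level discrete wavelet decomposition with 5th-order
Coiflets (coif5) splits the signal into frequency bands; drift (the deepest
approximation -- exactly zero for linear drift thanks to the Coiflet
vanishing moments) and high-frequency artefacts are removed by
reconstructing band-limited approximations.  Two of these, a1 (wider band,
keeps the sharp IC notch) and a2 (smoother, favours the broader FC notch),
drive the event search: per gait cycle the mid-swing time tms is the
positive peak of the denoised baseline, the IC is the most negative peak of
a1 in (tms + 0.25 s, tms + 2 s) and the FC the most negative peak of a2 in
(tms - 2 s, tms - 0.05 s), windows truncated at the neighbouring tms so no
cycle can claim another cycle's events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import find_peaks

from .events import EventSeries
from .io_formats import IMURecording, Placement


@dataclass(frozen=True)
class ShankDetectorConfig:
    wavelet: str = "coif5"
    decomposition_levels: int = 10
    #: IC search window offsets after tms, s
    ic_window: tuple[float, float] = (0.25, 2.0)
    #: FC search window offsets relative to tms, s (negative: before tms)
    fc_window: tuple[float, float] = (-2.0, -0.05)
    #: minimum mid-swing peak height as a fraction of the baseline maximum
    midswing_min_height_frac: float = 0.2
    midswing_min_separation: float = 0.5  # s
    #: retained frequency band (Hz) of the denoised baseline used for tms
    base_band: tuple[float, float] = (0.0, 8.0)
    #: retained band of approximation a1 (IC search: keeps the sharp notch)
    a1_band: tuple[float, float] = (0.0, 13.0)
    #: retained band of approximation a2 (FC search: smoother)
    a2_band: tuple[float, float] = (0.0, 5.0)

    def validate(self) -> None:
        if self.decomposition_levels < 1:
            raise ValueError("decomposition_levels must be >= 1")
        lo, hi = self.ic_window
        if not (0 < lo < hi):
            raise ValueError("ic_window offsets must be positive and ordered")
        lo, hi = self.fc_window
        if not (lo < hi < 0):
            raise ValueError("fc_window offsets must be negative and ordered")


@dataclass
class ShankDetectionIntermediate:
    """Band-limited approximations and mid-swing anchors for one shank."""

    baseline: np.ndarray
    approximation_a1: np.ndarray
    approximation_a2: np.ndarray
    fs: float
    effective_levels: int
    tms_times: np.ndarray = field(default_factory=lambda: np.array([]))


def _band_reconstruction(
    coeffs: list, fs: float, level: int, band: tuple[float, float], wavelet: str
) -> np.ndarray:
    """Reconstruct keeping only detail levels whose band overlaps ``band``.

    Detail level j spans roughly (fs / 2^(j+1), fs / 2^j); the deepest
    approximation (below fs / 2^(level+1)) is always suppressed, which is
    what removes drift.
    """
    lo, hi = band
    kept = [np.zeros_like(coeffs[0])]
    for i, d in enumerate(coeffs[1:], start=1):
        j = level - i + 1  # detail level of coeffs[i]
        f_lo, f_hi = fs / 2 ** (j + 1), fs / 2**j
        keep = (f_lo < hi) and (f_hi > lo)
        kept.append(d if keep else np.zeros_like(d))
    return pywt.waverec(kept, wavelet)


def wavelet_denoise_shank(
    sagittal_gyro: np.ndarray, fs: float, config: ShankDetectorConfig | None = None
) -> ShankDetectionIntermediate:
    """Decompose a shank sagittal gyro trace into the three approximations."""
    config = config or ShankDetectorConfig()
    config.validate()
    x = np.asarray(sagittal_gyro, dtype=float)
    max_level = pywt.dwt_max_level(x.size, config.wavelet)
    if max_level < 3:
        raise ValueError(
            f"signal too short for wavelet denoising: only {max_level} "
            f"decomposition level(s) feasible, need >= 3"
        )
    level = min(config.decomposition_levels, max_level)
    coeffs = pywt.wavedec(x, config.wavelet, mode="symmetric", level=level)
    n = x.size

    def recon(band):
        return _band_reconstruction(coeffs, fs, level, band, config.wavelet)[:n]

    return ShankDetectionIntermediate(
        baseline=recon(config.base_band),
        approximation_a1=recon(config.a1_band),
        approximation_a2=recon(config.a2_band),
        fs=fs,
        effective_levels=level,
    )


def detect_midswing_peaks(
    intermediate: ShankDetectionIntermediate,
    fs: float | None = None,
    config: ShankDetectorConfig | None = None,
) -> np.ndarray:
    """Per-cycle mid-swing anchors: positive peaks of the denoised baseline.

    The per-recording "global maximum" of the original description is read as
    the per-cycle maximum -- a single global peak could anchor only one cycle
    per recording -- with a relative height gate and a minimum separation.
    """
    config = config or ShankDetectorConfig()
    fs = fs or intermediate.fs
    base = intermediate.baseline
    if base.size == 0 or np.max(base) <= 0:
        return np.array([])
    height = config.midswing_min_height_frac * np.max(base)
    dist = max(1, int(round(config.midswing_min_separation * fs)))
    idx, _ = find_peaks(base, height=height, distance=dist)
    tms = idx / fs
    intermediate.tms_times = tms
    return tms


def _most_negative_peak(
    signal: np.ndarray, fs: float, t_lo: float, t_hi: float, t_anchor: float
) -> float | None:
    """Time of the most negative local minimum in (t_lo, t_hi), or None.

    Ties are broken toward the sample nearest the anchor (tms)."""
    i_lo = max(0, int(np.floor(t_lo * fs)) + 1)
    i_hi = min(signal.size - 1, int(np.ceil(t_hi * fs)) - 1)
    if i_hi - i_lo < 3:
        return None
    seg = signal[i_lo : i_hi + 1]
    idx, _ = find_peaks(-seg)
    idx = idx[seg[idx] < 0]
    if idx.size == 0:
        return None
    depth = seg[idx]
    best = depth.min()
    cands = idx[depth <= best + 1e-12]
    times = (cands + i_lo) / fs
    return float(times[np.argmin(np.abs(times - t_anchor))])


def detect_events_shank(
    sagittal_gyro: np.ndarray,
    fs: float,
    config: ShankDetectorConfig | None = None,
    side: str = "unassigned",
    placement: Placement | str = Placement.SHANK_RIGHT,
) -> EventSeries:
    """Detect one shank's ICs and FCs from its sagittal angular velocity."""
    config = config or ShankDetectorConfig()
    config.validate()
    inter = wavelet_denoise_shank(sagittal_gyro, fs, config)
    tms = detect_midswing_peaks(inter, fs, config)
    diagnostics = {"n_tms": int(tms.size), "n_dropped_cycles": 0,
                   "effective_levels": inter.effective_levels}
    if tms.size == 0:
        diagnostics["warning"] = "no mid-swing peaks above threshold"
        return EventSeries(placement, side, np.array([]), np.array([]), diagnostics)

    duration = (sagittal_gyro.size - 1) / fs
    ics, fcs = [], []
    for k, t in enumerate(tms):
        ic_lo = t + config.ic_window[0]
        ic_hi = min(t + config.ic_window[1], duration)
        if k + 1 < tms.size:
            ic_hi = min(ic_hi, tms[k + 1])
        fc_lo = max(t + config.fc_window[0], 0.0)
        if k > 0:
            fc_lo = max(fc_lo, tms[k - 1])
        fc_hi = t + config.fc_window[1]

        ic = _most_negative_peak(inter.approximation_a1, fs, ic_lo, ic_hi, t)
        fc = _most_negative_peak(inter.approximation_a2, fs, fc_lo, fc_hi, t)
        if ic is None or fc is None:
            diagnostics["n_dropped_cycles"] += 1
            if ic is not None:
                ics.append(ic)
            if fc is not None:
                fcs.append(fc)
            continue
        ics.append(ic)
        fcs.append(fc)

    ics = np.unique(np.asarray(ics))
    fcs = np.unique(np.asarray(fcs))
    diagnostics["n_ic"] = int(ics.size)
    diagnostics["n_fc"] = int(fcs.size)
    return EventSeries(placement, side, ics, fcs, diagnostics)


def detect_events_shank_recording(
    rec: IMURecording, config: ShankDetectorConfig | None = None
) -> EventSeries:
    """Convenience wrapper: pick the sagittal channel and side from the recording."""
    side = {"shank_left": "L", "shank_right": "R"}.get(rec.placement.value, "unassigned")
    return detect_events_shank(
        rec.sagittal_gyro(), rec.fs, config, side=side, placement=rec.placement
    )
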