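from dataclasses import replace

import numpy as np
import pytest

from imugait.lumbar import tilt_correct_to_vertical
from imugait.shank import wavelet_denoise_shank
from imugait.synthetic_gait import (
    COHORT_PRESETS,
    CohortPreset,
    indoor_preset,
    make_gait_script,
    single_bout_preset,
    synthesize_lumbar_accel,
    synthesize_shank_gyro,
    treadmill_preset,
)

YA = COHORT_PRESETS["YA"]


def deterministic_preset(**overrides):
    base = dict(
        name="test", stride_mean=1.1, stride_sd=0.0, stance_fraction_sd=0.0,
        step_asymmetry_offset=0.0,
    )
    base.update(overrides)
    return CohortPreset(**base)


class TestGaitScript:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            make_gait_script(YA, single_bout_preset(10), seed=None)

    def test_zero_sd_gives_exact_strides_and_steps(self):
        script = make_gait_script(deterministic_preset(), single_bout_preset(30), seed=0)
        for side in "LR":
            np.testing.assert_allclose(np.diff(script.ic_times(side)), 1.1, atol=1e-12)
        both = script.all_ic_times()
        np.testing.assert_allclose(np.diff(both), 0.55, atol=1e-12)

    def test_ya_stride_mean_recovers_preset(self):
        script = make_gait_script(YA, single_bout_preset(60), seed=2)
        strides = np.concatenate([script.stride_times(s) for s in "LR"])
        # consecutive strides share a step, so the mean's SE carries a
        # factor sqrt(2) relative to the iid formula
        se = np.sqrt(2.0) * YA.stride_sd / np.sqrt(strides.size)
        assert abs(strides.mean() - 1.096) < 2 * se + 1e-9

    def test_stride_sd_monte_carlo(self):
        # ~5000 strides: one long bout
        preset = deterministic_preset(stride_sd=0.04)
        script = make_gait_script(preset, single_bout_preset(2800), seed=3)
        strides = np.concatenate([script.stride_times(s) for s in "LR"])
        assert strides.size > 4500
        assert 0.038 < strides.std(ddof=1) < 0.042

    @pytest.mark.parametrize("cohort", ["YA", "OA", "PD"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_event_ordering_invariant(self, cohort, seed):
        script = make_gait_script(COHORT_PRESETS[cohort], indoor_preset(), seed=seed)
        for side in "LR":
            ics, fcs = script.ic_times(side), script.fc_times(side)
            for ic, next_ic in zip(ics[:-1], ics[1:]):
                inside = fcs[(fcs > ic) & (fcs < next_ic)]
                if next_ic - ic > 2.5:  # bout gap: no cycle, no FC
                    assert inside.size == 0
                    continue
                assert inside.size == 1
                sf = (inside[0] - ic) / (next_ic - ic)
                assert 0.4 < sf < 0.8

    def test_ics_alternate_within_bouts(self):
        script = make_gait_script(YA, indoor_preset(), seed=4)
        for bout in script.bouts:
            labels = []
            for side in "LR":
                for t in script.ic_times(side):
                    if bout.start <= t <= bout.stop:
                        labels.append((t, side))
            labels.sort()
            sides = [s for _, s in labels]
            assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_bout_gaps_contain_no_events(self):
        script = make_gait_script(YA, indoor_preset(), seed=4)
        events = np.concatenate(
            [script.all_ic_times(), script.all_fc_times()]
        )
        for b0, b1 in zip(script.bouts, script.bouts[1:]):
            assert not np.any((events > b0.stop) & (events < b1.start))

    def test_same_seed_bit_identical(self):
        a = make_gait_script(YA, single_bout_preset(30), seed=9)
        b = make_gait_script(YA, single_bout_preset(30), seed=9)
        np.testing.assert_array_equal(a.ic_left, b.ic_left)
        ra = synthesize_lumbar_accel(a, 100, noise_sd=0.1, seed=9)
        rb = synthesize_lumbar_accel(b, 100, noise_sd=0.1, seed=9)
        np.testing.assert_array_equal(ra.accel, rb.accel)

    def test_treadmill_has_seven_stages(self):
        env = treadmill_preset()
        assert len(env.bouts) == 7
        scales = [b.stride_scale for b in env.bouts]
        assert scales == sorted(scales, reverse=True)  # faster belt, shorter stride
        with pytest.raises(ValueError):
            treadmill_preset(speeds_kmh=(2, 3, 4))


class TestLumbarWaveform:
    def test_gravity_baseline_exact(self, ya_script):
        rec = synthesize_lumbar_accel(ya_script, 100, noise_sd=0.0, tilt_deg=0.0)
        assert abs(rec.accel[:, 2].mean() - 9.81) < 1e-6

    def test_tilt_then_correct_recovers_vertical(self, ya_script):
        flat = synthesize_lumbar_accel(ya_script, 100, noise_sd=0.0, tilt_deg=0.0)
        tilted = synthesize_lumbar_accel(ya_script, 100, noise_sd=0.0, tilt_deg=10.0)
        vertical, _ = tilt_correct_to_vertical(tilted)
        rms = np.sqrt(np.mean((vertical - flat.accel[:, 2]) ** 2))
        amplitude = np.ptp(flat.accel[:, 2])
        assert rms < 1e-6 * amplitude

    def test_empty_script_rejected(self):
        empty = make_gait_script(YA, single_bout_preset(10), seed=0)
        empty.ic_left = empty.ic_right = np.array([])
        empty.fc_left = empty.fc_right = np.array([])
        with pytest.raises(ValueError):
            synthesize_lumbar_accel(empty, 100, noise_sd=0.0)


class TestShankWaveform:
    def test_midswing_lobe_peaks_at_scripted_time(self, ya_script,
                                                  shank_recordings_clean):
        fs = 100.0
        sag = shank_recordings_clean["L"].sagittal_gyro()
        for tms in ya_script.midswing_times("L")[2:-2]:
            i = int(round(tms * fs))
            w = int(0.1 * fs)
            local = sag[i - w : i + w + 1]
            assert abs(np.argmax(local) - w) <= 1

    def test_absent_side_rejected(self, ya_script):
        script = make_gait_script(YA, single_bout_preset(20), seed=1)
        script.ic_right = np.array([])
        with pytest.raises(ValueError, match="side"):
            synthesize_shank_gyro(script, "R", 100, noise_sd=0.0)

    def test_amplitude_linearity(self, ya_script):
        kw = dict(fs=100.0, noise_sd=0.0, drift_rate=0.0)
        base = synthesize_shank_gyro(ya_script, "L", **kw)
        doubled = synthesize_shank_gyro(
            ya_script, "L", midswing_amplitude=2 * 250.0,
            ic_notch_depth=2 * 180.0, fc_notch_depth=2 * 150.0, **kw,
        )
        np.testing.assert_allclose(
            doubled.sagittal_gyro(), 2 * base.sagittal_gyro(), atol=1e-9
        )

    def test_drift_visible_raw_and_removed_by_denoising(self):
        script = make_gait_script(YA, single_bout_preset(120), seed=2)
        rec = synthesize_shank_gyro(script, "L", 100, noise_sd=0.0, drift_rate=0.5)
        flat = synthesize_shank_gyro(script, "L", 100, noise_sd=0.0, drift_rate=0.0)
        endpoint_offset = rec.sagittal_gyro()[-1] - flat.sagittal_gyro()[-1]
        assert abs(endpoint_offset - 0.5 * rec.t[-1]) < 1e-9
        inter = wavelet_denoise_shank(rec.sagittal_gyro(), 100)
        assert abs(inter.baseline.mean()) < 2.0  # deg/s


class TestSubjectSampling:
    def test_subject_presets_vary_but_are_reproducible(self):
        r1 = np.random.default_rng(7)
        r2 = np.random.default_rng(7)
        a = YA.sample_subject(r1)
        b = YA.sample_subject(r2)
        assert a == b
        assert a.stride_mean != YA.stride_mean  # between-subject draw applied
        assert a.stride_mean >= 1.0

    def test_invalid_presets_rejected(self):
        with pytest.raises(ValueError):
            CohortPreset(name="x", stride_mean=-1.0, stride_sd=0.0)
        with pytest.raises(ValueError):
            CohortPreset(name="x", stride_mean=1.0, stride_sd=0.0,
                         midswing_amplitude=-5.0)
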