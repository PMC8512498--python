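import numpy as np
import pytest

from imugait.events import EventSeries
from imugait.io_formats import Placement
from imugait.synthetic_gait import (
    COHORT_PRESETS,
    CohortPreset,
    make_gait_script,
    single_bout_preset,
)
from imugait.temporal import (
    assign_sides_lumbar,
    build_gait_cycles,
    compute_temporal_series,
    summarize_events,
    summarize_temporal,
)


def _events(side, ics, fcs):
    placement = Placement.SHANK_LEFT if side == "L" else Placement.SHANK_RIGHT
    return EventSeries(placement, side, np.asarray(ics, float), np.asarray(fcs, float))


def _script_events(script):
    return (
        _events("L", script.ic_left, script.fc_left),
        _events("R", script.ic_right, script.fc_right),
    )


class TestBuildCycles:
    def test_minimal_left_cycle(self):
        cycles = build_gait_cycles(
            _events("L", [0.0, 1.2], [0.7]), _events("R", [0.6], [])
        )
        assert len(cycles) == 1
        row = cycles.iloc[0]
        assert (row.side, row.ic, row.fc, row.next_ic, row.contra_ic) == (
            "L", 0.0, 0.7, 1.2, 0.6,
        )

    def test_cycle_with_two_fcs_dropped_with_diagnostic(self):
        cycles = build_gait_cycles(
            _events("L", [0.0, 1.2], [0.5, 0.8]), _events("R", [], [])
        )
        assert len(cycles) == 0
        assert cycles.attrs["diagnostics"]["dropped_extra_fc"] == 1

    def test_cycle_without_fc_dropped(self):
        cycles = build_gait_cycles(
            _events("L", [0.0, 1.2], [1.5]), _events("R", [], [])
        )
        assert len(cycles) == 0
        assert cycles.attrs["diagnostics"]["dropped_no_fc"] == 1

    def test_bout_gap_cycles_dropped(self):
        cycles = build_gait_cycles(
            _events("L", [0.0, 1.1, 5.0, 6.1], [0.7, 5.7]), _events("R", [], [])
        )
        assert len(cycles) == 2
        assert cycles.attrs["diagnostics"]["dropped_gap"] == 1

    def test_unordered_input_rejected(self):
        with pytest.raises(ValueError):
            ev = _events("L", [0.0, 1.0], [])
            ev.ic_times = np.array([1.0, 0.0])
            build_gait_cycles(ev, _events("R", [], []))

    def test_cycle_count_matches_script_oracle(self, ya_script):
        left, right = _script_events(ya_script)
        cycles = build_gait_cycles(left, right)
        # single bout: every consecutive same-side IC pair has exactly one FC
        expected = (ya_script.ic_left.size - 1) + (ya_script.ic_right.size - 1)
        assert len(cycles) == expected


class TestTemporalSeries:
    def test_arithmetic_of_minimal_cycle(self):
        cycles = build_gait_cycles(
            _events("L", [0.0, 1.2], [0.7]), _events("R", [0.6], [])
        )
        series = compute_temporal_series(cycles)
        row = series.iloc[0]
        assert row.stride == pytest.approx(1.2)
        assert row.stance == pytest.approx(0.7)
        assert row.swing == pytest.approx(0.5)
        assert row.step == pytest.approx(0.6)
        assert row.step_side == "R"

    def test_stride_is_exactly_stance_plus_swing(self, ya_script):
        left, right = _script_events(ya_script)
        series = compute_temporal_series(build_gait_cycles(left, right))
        np.testing.assert_array_equal(
            series.stride.to_numpy(),
            (series.stance + series.swing).to_numpy(),
        )
        assert (series.step < series.stride).all()

    def test_stance_fraction_recovered(self):
        preset = CohortPreset(name="t", stride_mean=1.1, stride_sd=0.02,
                              stance_fraction_mean=0.60, stance_fraction_sd=0.01)
        script = make_gait_script(preset, single_bout_preset(60), seed=3)
        series = compute_temporal_series(
            build_gait_cycles(*_script_events(script))
        )
        frac = (series.stance / series.stride).mean()
        assert 0.58 < frac < 0.62


class TestSummaries:
    def test_two_point_sd(self):
        cycles = build_gait_cycles(
            _events("L", [0.0, 1.0, 2.2], [0.6, 1.7]), _events("R", [], [])
        )
        summary = summarize_temporal(compute_temporal_series(cycles))
        assert summary.value("stride", "mean") == pytest.approx(1.1)
        assert summary.value("stride", "variability") == pytest.approx(
            np.std([1.0, 1.2], ddof=1)
        )

    def test_symmetric_script_has_zero_asymmetry(self):
        preset = CohortPreset(name="t", stride_mean=1.1, stride_sd=0.0,
                              stance_fraction_sd=0.0, step_asymmetry_offset=0.0)
        script = make_gait_script(preset, single_bout_preset(40), seed=0)
        summary = summarize_events(*_script_events(script))
        for param in ("stride", "stance", "swing", "step"):
            assert summary.value(param, "asymmetry") == pytest.approx(0.0, abs=1e-9)

    def test_step_asymmetry_offset_recovered(self):
        preset = CohortPreset(name="t", stride_mean=1.1, stride_sd=0.02,
                              stance_fraction_sd=0.01, step_asymmetry_offset=0.02)
        script = make_gait_script(preset, single_bout_preset(120), seed=5)
        summary = summarize_events(*_script_events(script))
        assert 0.015 < summary.value("step", "asymmetry") < 0.025

    def test_summaries_invariant_to_global_time_shift(self, ya_script):
        left, right = _script_events(ya_script)
        base = summarize_events(left, right)
        shifted = summarize_events(left.shifted(100.0), right.shifted(100.0))
        np.testing.assert_allclose(
            base.values.to_numpy(), shifted.values.to_numpy(), atol=1e-9
        )

    def test_too_few_cycles_flagged_not_zero(self):
        summary = summarize_events(_events("L", [0.0, 1.1], [0.7]),
                                   _events("R", [], []))
        assert np.isnan(summary.value("stride", "asymmetry"))
        assert any("asymmetry" in f for f in summary.flags)

    def test_mean_stride_equals_mean_stance_plus_swing(self, ya_script):
        summary = summarize_events(*_script_events(ya_script))
        assert summary.value("stride", "mean") == pytest.approx(
            summary.value("stance", "mean") + summary.value("swing", "mean"),
            abs=1e-12,
        )

    def test_alternative_definitions_exposed(self, ya_script):
        left, right = _script_events(ya_script)
        cycles = build_gait_cycles(left, right)
        series = compute_temporal_series(cycles)
        a = summarize_temporal(series, variability="mean_side_sd",
                               asymmetry="mean_abs_diff")
        b = summarize_temporal(series)
        assert a.value("stride", "variability") > 0
        assert a.value("step", "asymmetry") >= b.value("step", "asymmetry") - 1e-12
        with pytest.raises(ValueError):
            summarize_temporal(series, variability="bogus")


class TestSideAssignment:
    def test_alternation_mode_recovers_sides(self, ya_script, lumbar_events_clean):
        left, right = assign_sides_lumbar(lumbar_events_clean)
        # alternation starts from the first event; scripted first IC is left
        from imugait.metrics import match_events

        m = match_events(left.ic_times, ya_script.ic_left, tolerance=0.05)
        assert m.recall > 0.9

    def test_shank_anchored_assignment(self, ya_script, lumbar_events_clean,
                                       shank_events_clean):
        left, right = assign_sides_lumbar(
            lumbar_events_clean, shank_events_clean["L"], shank_events_clean["R"]
        )
        from imugait.metrics import match_events

        for ev, side in ((left, "L"), (right, "R")):
            m = match_events(ev.ic_times, ya_script.ic_times(side), tolerance=0.05)
            assert m.recall > 0.9
            assert m.precision > 0.95
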