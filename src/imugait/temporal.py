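"""Gait cycle assembly and temporal parameter summaries.

From per-side IC/FC event series this module builds gait cycles (consecutive
same-side ICs with the unique FC strictly between them), derives the per-cycle
temporal parameters

* stride time = IC(k+1) - IC(k)            (same side)
* stance time = FC(k) - IC(k)
* swing  time = IC(k+1) - FC(k)            (stride = stance + swing, exactly)
* step   time = IC - preceding contralateral IC (needs both feet)

and summarises them per subject as mean, variability (SD over cycles, both
sides pooled) and asymmetry (|left mean - right mean|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventSeries

#: cycles whose stride exceeds this are assumed to bridge a bout gap (turns,
#: standing) and are dropped rather than counted as gait
MAX_STRIDE_GAP = 2.5

PARAMETERS = ("stride", "stance", "swing", "step")
STATISTICS = ("mean", "variability", "asymmetry")


def assign_sides_lumbar(
    lumbar: EventSeries,
    shank_left: EventSeries | None = None,
    shank_right: EventSeries | None = None,
    max_match_gap: float = 0.3,
) -> tuple[EventSeries, EventSeries]:
    """Split side-unassigned lumbar events into left/right series.

    When both shank event series are available each lumbar IC takes the side
    of the nearest-in-time shank IC (and each FC the side of the nearest
    shank FC); lumbar events farther than ``max_match_gap`` from any shank
    event of the same type are treated as spurious (the lumbar chain's
    "extra events" failure mode, typically in bout gaps) and discarded with
    a diagnostic count.  In lumbar-only mode sides alternate starting from
    the first event, and each FC inherits the side of its own cycle (the
    side opposite the nearest preceding IC, since the contralateral foot
    strikes between a foot's IC and its FC); this alternation is a
    documented approximation.
    """
    ics, fcs = lumbar.ic_times, lumbar.fc_times
    n_spurious = 0
    if shank_left is not None and shank_right is not None and (
        shank_left.ic_times.size and shank_right.ic_times.size
    ):
        def nearest_side(times, left_ref, right_ref):
            nonlocal n_spurious
            sides = []
            for t in times:
                dl = np.min(np.abs(left_ref - t)) if left_ref.size else np.inf
                dr = np.min(np.abs(right_ref - t)) if right_ref.size else np.inf
                if min(dl, dr) > max_match_gap:
                    sides.append("spurious")
                    n_spurious += 1
                else:
                    sides.append("L" if dl <= dr else "R")
            return np.asarray(sides)

        ic_sides = nearest_side(ics, shank_left.ic_times, shank_right.ic_times)
        fc_sides = nearest_side(fcs, shank_left.fc_times, shank_right.fc_times)
    else:
        ic_sides = np.asarray(["L" if k % 2 == 0 else "R" for k in range(ics.size)])
        fc_sides = []
        for t in fcs:
            prev = np.flatnonzero(ics < t)
            if prev.size:
                fc_sides.append("R" if ic_sides[prev[-1]] == "L" else "L")
            else:
                fc_sides.append("L")
        fc_sides = np.asarray(fc_sides)

    out = []
    for side in ("L", "R"):
        out.append(
            EventSeries(
                lumbar.placement,
                side,
                ics[ic_sides == side] if ics.size else np.array([]),
                fcs[fc_sides == side] if fcs.size else np.array([]),
                {"assigned_from": "shank" if shank_left is not None else "alternation",
                 "n_spurious_dropped": n_spurious},
            )
        )
    return out[0], out[1]


def build_gait_cycles(
    left: EventSeries,
    right: EventSeries,
    max_stride_gap: float = MAX_STRIDE_GAP,
) -> pd.DataFrame:
    """Pair per-side events into gait cycles.

    Returns a DataFrame with columns ``side, cycle_index, ic, fc, next_ic,
    contra_ic`` (NaN when no contralateral IC falls strictly inside the
    cycle).  Cycles lacking a unique FC strictly between their ICs, or
    spanning a bout gap, are dropped and counted in ``df.attrs['diagnostics']``.
    """
    series = {"L": left, "R": right}
    diagnostics = {"dropped_no_fc": 0, "dropped_extra_fc": 0, "dropped_gap": 0}
    rows = []
    for side, ev in series.items():
        if ev.ic_times.size > 1 and np.any(np.diff(ev.ic_times) <= 0):
            raise ValueError("event series must be ordered")
        contra = series["R" if side == "L" else "L"].ic_times
        ics, fcs = ev.ic_times, ev.fc_times
        for k in range(ics.size - 1):
            ic, next_ic = ics[k], ics[k + 1]
            if next_ic - ic > max_stride_gap:
                diagnostics["dropped_gap"] += 1
                continue
            inside = fcs[(fcs > ic) & (fcs < next_ic)]
            if inside.size == 0:
                diagnostics["dropped_no_fc"] += 1
                continue
            if inside.size > 1:
                diagnostics["dropped_extra_fc"] += 1
                continue
            c_inside = contra[(contra > ic) & (contra < next_ic)]
            rows.append(
                (side, k, ic, float(inside[0]), next_ic,
                 float(c_inside[0]) if c_inside.size else np.nan)
            )
    df = pd.DataFrame(rows, columns=["side", "cycle_index", "ic", "fc", "next_ic", "contra_ic"])
    if not df.empty:
        df = df.sort_values(["side", "ic"]).reset_index(drop=True)
    df.attrs["diagnostics"] = diagnostics
    return df


def compute_temporal_series(cycles: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle stride/stance/swing/step times from a cycle table.

    The step attributed to a row is the interval from the row's IC to the
    contralateral IC inside the cycle -- i.e. the *contralateral* foot's
    step -- so ``step_side`` is the opposite of ``side``.  Rows without a
    contralateral IC get NaN step entries.
    """
    if cycles.empty:
        return pd.DataFrame(
            columns=["side", "stride", "stance", "swing", "step", "step_side"]
        )
    out = pd.DataFrame(
        {
            "side": cycles["side"],
            "stride": cycles["next_ic"] - cycles["ic"],
            "stance": cycles["fc"] - cycles["ic"],
            "swing": cycles["next_ic"] - cycles["fc"],
            "step": cycles["contra_ic"] - cycles["ic"],
            "step_side": np.where(cycles["side"] == "L", "R", "L"),
        }
    )
    bad = (out["stride"] <= 0) | (out["stance"] <= 0) | (out["swing"] <= 0)
    if bad.any():
        raise ValueError("cycle table violates IC < FC < next IC ordering")
    return out


@dataclass
class TemporalSummary:
    """Per-subject mean / variability / asymmetry of the four parameters.

    Entries that cannot be computed (too few cycles) are NaN and listed in
    ``flags``.
    """

    values: pd.DataFrame  # index: parameter, columns: mean, variability, asymmetry
    n_cycles: int
    flags: list

    def value(self, parameter: str, statistic: str) -> float:
        return float(self.values.loc[parameter, statistic])

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df["n_cycles"] = self.n_cycles
        return df


def summarize_temporal(
    series: pd.DataFrame,
    variability: str = "pooled_sd",
    asymmetry: str = "abs_mean_diff",
) -> TemporalSummary:
    """Summarise a per-cycle table into one subject-level record.

    ``variability``: ``"pooled_sd"`` (sample SD over all cycles, both sides)
    or ``"mean_side_sd"`` (mean of per-side SDs).  ``asymmetry``:
    ``"abs_mean_diff"`` (|left mean - right mean|) or ``"mean_abs_diff"``
    (mean |left - right| over cycle pairs matched by order).
    """
    if variability not in ("pooled_sd", "mean_side_sd"):
        raise ValueError(f"unknown variability definition {variability!r}")
    if asymmetry not in ("abs_mean_diff", "mean_abs_diff"):
        raise ValueError(f"unknown asymmetry definition {asymmetry!r}")

    flags = []
    rows = {}
    for param in PARAMETERS:
        if param == "step":
            vals = series.dropna(subset=["step"]) if not series.empty else series
            values = vals["step"].to_numpy() if not series.empty else np.array([])
            sides = vals["step_side"].to_numpy() if not series.empty else np.array([])
        else:
            values = series[param].to_numpy() if not series.empty else np.array([])
            sides = series["side"].to_numpy() if not series.empty else np.array([])
        left = values[sides == "L"]
        right = values[sides == "R"]

        mean = float(np.mean(values)) if values.size else np.nan
        if values.size >= 2:
            if variability == "pooled_sd":
                var = float(np.std(values, ddof=1))
            else:
                per_side = [np.std(v, ddof=1) for v in (left, right) if v.size >= 2]
                var = float(np.mean(per_side)) if per_side else np.nan
        else:
            var = np.nan
            flags.append(f"{param}: <2 cycles, variability undefined")
        if left.size >= 2 and right.size >= 2:
            if asymmetry == "abs_mean_diff":
                asym = float(abs(left.mean() - right.mean()))
            else:
                m = min(left.size, right.size)
                asym = float(np.mean(np.abs(left[:m] - right[:m])))
        else:
            asym = np.nan
            flags.append(f"{param}: <2 cycles per side, asymmetry undefined")
        if not values.size:
            flags.append(f"{param}: no cycles")
        rows[param] = (mean, var, asym)

    values_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(STATISTICS)
    ).rename_axis("parameter")
    return TemporalSummary(values=values_df, n_cycles=int(len(series)), flags=flags)


def summarize_events(
    left: EventSeries,
    right: EventSeries,
    variability: str = "pooled_sd",
    asymmetry: str = "abs_mean_diff",
) -> TemporalSummary:
    """Events -> cycles -> series -> summary in one call."""
    cycles = build_gait_cycles(left, right)
    series = compute_temporal_series(cycles)
    summary = summarize_temporal(series, variability=variability, asymmetry=asymmetry)
    summary.flags.extend(
        f"cycles {k}={v}" for k, v in cycles.attrs["diagnostics"].items() if v
    )
    return summary
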