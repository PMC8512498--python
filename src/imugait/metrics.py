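"""Event-matching utilities for evaluating detectors against a gait script."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MatchResult:
    """One-to-one greedy matching of detected events to reference events."""

    n_reference: int
    n_detected: int
    errors: np.ndarray  # detected - reference, s, one per matched pair

    @property
    def n_matched(self) -> int:
        return int(self.errors.size)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_reference if self.n_reference else np.nan

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else np.nan

    @property
    def median_abs_error(self) -> float:
        return float(np.median(np.abs(self.errors))) if self.errors.size else np.nan


def match_events(detected, reference, tolerance: float = 0.05) -> MatchResult:
    """Greedy one-to-one matching by increasing |time difference|.

    Each detected event may claim at most one reference event within
    ``tolerance`` seconds and vice versa; closest pairs are matched first.
    """
    det = np.sort(np.asarray(detected, dtype=float))
    ref = np.sort(np.asarray(reference, dtype=float))
    if det.size == 0 or ref.size == 0:
        return MatchResult(ref.size, det.size, np.array([]))
    diff = det[:, None] - ref[None, :]
    cand = np.argwhere(np.abs(diff) <= tolerance)
    order = np.argsort(np.abs(diff[cand[:, 0], cand[:, 1]]), kind="stable")
    used_d = np.zeros(det.size, bool)
    used_r = np.zeros(ref.size, bool)
    errors = []
    for i, j in cand[order]:
        if not used_d[i] and not used_r[j]:
            used_d[i] = used_r[j] = True
            errors.append(diff[i, j])
    return MatchResult(ref.size, det.size, np.asarray(errors))
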