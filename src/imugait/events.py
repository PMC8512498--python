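"""Detected gait event containers shared by both detectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Placement


@dataclass
class EventSeries:
    """Detected initial-contact (IC) and final-contact (FC) times, seconds.

    ``side`` is ``"L"``, ``"R"`` or ``"unassigned"`` (the lumbar detector sees
    both feet and cannot attribute events to a side on its own).
    """

    placement: Placement
    side: str
    ic_times: np.ndarray
    fc_times: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        if self.side not in ("L", "R", "unassigned"):
            raise ValueError(f"side must be 'L', 'R' or 'unassigned', got {self.side!r}")
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        for name, arr in (("ic_times", self.ic_times), ("fc_times", self.fc_times)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly ascending")

    @property
    def n_events(self) -> int:
        return int(self.ic_times.size + self.fc_times.size)

    def shifted(self, offset: float) -> "EventSeries":
        return EventSeries(
            self.placement,
            self.side,
            self.ic_times + offset,
            self.fc_times + offset,
            dict(self.diagnostics),
        )
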