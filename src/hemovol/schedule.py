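"""Piecewise-constant hemorrhage / infusion input schedules.

An :class:`InputSchedule` holds non-overlapping time segments, each carrying
a constant infusion rate ``u`` (external fluid gain, L/min) and a constant
loss rate ``v`` (hemorrhage + other external losses, L/min).  Gaps between
segments mean zero rates.  Cumulative inputs are therefore piecewise linear
and computed exactly, which both the adaptive and the fixed-step integrators
rely on (solver restarts at segment breakpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Segment", "InputSchedule"]

SCHEDULE_COLUMNS = ("t_start_min", "t_end_min", "u_rate_L_per_min", "v_rate_L_per_min")


@dataclass(frozen=True)
class Segment:
    t_start: float
    t_end: float
    u_rate: float = 0.0
    v_rate: float = 0.0


class InputSchedule:
    """Ordered, non-overlapping input segments covering [0, horizon]."""

    def __init__(self, segments: Sequence[Segment | tuple], horizon: float) -> None:
        segs = [s if isinstance(s, Segment) else Segment(*s) for s in segments]
        segs = sorted(segs, key=lambda s: s.t_start)
        if horizon <= 0 or not np.isfinite(horizon):
            raise ValueError(f"horizon must be finite and > 0, got {horizon}")
        for s in segs:
            if not (0.0 <= s.t_start < s.t_end <= horizon):
                raise ValueError(f"segment [{s.t_start}, {s.t_end}] outside [0, {horizon}]")
            if s.u_rate < 0 or s.v_rate < 0:
                raise ValueError("rates must be non-negative")
            if not np.all(np.isfinite([s.t_start, s.t_end, s.u_rate, s.v_rate])):
                raise ValueError("segment values must be finite")
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError(
                    f"segments [{a.t_start},{a.t_end}] and [{b.t_start},{b.t_end}] overlap"
                )
        self.segments: tuple[Segment, ...] = tuple(segs)
        self.horizon = float(horizon)
        self._build_intervals()

    def _build_intervals(self) -> None:
        # Closed partition of [0, horizon] into constant-rate intervals,
        # with exact cumulative integrals at the interval edges.
        edges = {0.0, self.horizon}
        for s in self.segments:
            edges.add(s.t_start)
            edges.add(s.t_end)
        t = np.array(sorted(edges))
        u = np.zeros(len(t) - 1)
        v = np.zeros(len(t) - 1)
        for s in self.segments:
            inside = (t[:-1] >= s.t_start - 1e-12) & (t[1:] <= s.t_end + 1e-12)
            u[inside] += s.u_rate
            v[inside] += s.v_rate
        dt = np.diff(t)
        self.edges = t
        self.u_rates = u
        self.v_rates = v
        self.cum_u_edges = np.concatenate([[0.0], np.cumsum(u * dt)])
        self.cum_v_edges = np.concatenate([[0.0], np.cumsum(v * dt)])

    # -- evaluation ---------------------------------------------------------

    def _interval_index(self, t: float) -> int:
        idx = int(np.searchsorted(self.edges, t, side="right") - 1)
        return min(max(idx, 0), len(self.u_rates) - 1)

    def rates(self, t: float) -> tuple[float, float]:
        """(u(t), v(t)) in L/min; zero outside [0, horizon]."""
        if t < 0 or t > self.horizon:
            return 0.0, 0.0
        k = self._interval_index(t)
        return float(self.u_rates[k]), float(self.v_rates[k])

    def cumulative(self, t: float) -> tuple[float, float]:
        """Exact (int_0^t u, int_0^t v) in L (piecewise linear)."""
        if t <= 0:
            return 0.0, 0.0
        t = min(t, self.horizon)
        k = self._interval_index(t)
        dt = t - self.edges[k]
        return (
            float(self.cum_u_edges[k] + self.u_rates[k] * dt),
            float(self.cum_v_edges[k] + self.v_rates[k] * dt),
        )

    def totals(self) -> tuple[float, float]:
        """(U_tot, V_tot): total fluid gained / lost over the horizon, L."""
        return float(self.cum_u_edges[-1]), float(self.cum_v_edges[-1])

    @property
    def breakpoints(self) -> np.ndarray:
        return self.edges

    # -- composition --------------------------------------------------------

    def with_segments(self, extra: Sequence[Segment | tuple]) -> "InputSchedule":
        """New schedule with additional segments merged in (rates add)."""
        extra_segs = [s if isinstance(s, Segment) else Segment(*s) for s in extra]
        merged = _merge_segments(list(self.segments) + extra_segs, self.horizon)
        return InputSchedule(merged, self.horizon)

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start_min": [s.t_start for s in self.segments],
                "t_end_min": [s.t_end for s in self.segments],
                "u_rate_L_per_min": [s.u_rate for s in self.segments],
                "v_rate_L_per_min": [s.v_rate for s in self.segments],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, horizon: float | None = None) -> "InputSchedule":
        missing = set(SCHEDULE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"schedule table missing columns: {sorted(missing)}")
        segs = [
            Segment(r.t_start_min, r.t_end_min, r.u_rate_L_per_min, r.v_rate_L_per_min)
            for r in frame.itertuples()
        ]
        if horizon is None:
            horizon = max(s.t_end for s in segs) if segs else 180.0
        return cls(segs, horizon)

    @classmethod
    def from_csv(cls, path, horizon: float | None = None) -> "InputSchedule":
        return cls.from_frame(pd.read_csv(path), horizon=horizon)

    def __repr__(self) -> str:
        return f"InputSchedule({len(self.segments)} segments, horizon={self.horizon} min)"


def _merge_segments(segments: list[Segment], horizon: float) -> list[Segment]:
    """Split overlapping segments on a common edge grid, summing rates."""
    edges = sorted({0.0, horizon, *(s.t_start for s in segments), *(s.t_end for s in segments)})
    out: list[Segment] = []
    for a, b in zip(edges, edges[1:]):
        mid = 0.5 * (a + b)
        u = sum(s.u_rate for s in segments if s.t_start <= mid < s.t_end)
        v = sum(s.v_rate for s in segments if s.t_start <= mid < s.t_end)
        if u > 0 or v > 0:
            out.append(Segment(a, b, u, v))
    return out
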