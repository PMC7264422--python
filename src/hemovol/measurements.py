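"""Measurement containers: sampled signals, availability masks, noise model.

The three measured signals are blood volume ("bv", L), cardiac output
("co", L/min) and mean arterial pressure ("map", mmHg).  The availability
mask encodes the data-scarcity cases:

* case 1 — {"bv", "co", "map"} (all signals fitted),
* case 2 — {"co", "map"} (BV withheld),
* case 3 — {"map"} (BV and CO withheld).

Masked-out signals stay in the container so they can score internal-state
predictions (the e2 metric); they never enter the fit cost J1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import SubjectContext
from .schedule import InputSchedule

__all__ = ["SIGNALS", "CASE_MASKS", "NoiseModel", "MeasurementSet", "SubjectRecord"]

SIGNALS: tuple[str, ...] = ("bv", "co", "map")

#: Fitted-signal masks for the three data-scarcity cases.
CASE_MASKS: dict[int, frozenset[str]] = {
    1: frozenset({"bv", "co", "map"}),
    2: frozenset({"co", "map"}),
    3: frozenset({"map"}),
}

_CSV_COLUMNS = {"bv": "BV_L", "co": "CO_L_per_min", "map": "MAP_mmHg"}


@dataclass(frozen=True)
class NoiseModel:
    """Per-signal measurement noise SDs (diagonal covariance).

    Defaults are the package's nominal instrument-noise calibration:
    0.1 L for dilution-based BV, 0.3 L/min for flow-probe CO, 5 mmHg for
    catheter MAP.  They are configurable, not measured values.
    """

    sigma_bv: float = 0.1
    sigma_co: float = 0.3
    sigma_map: float = 5.0

    def __post_init__(self) -> None:
        for name in ("sigma_bv", "sigma_co", "sigma_map"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def sigma(self, signal: str) -> float:
        return {"bv": self.sigma_bv, "co": self.sigma_co, "map": self.sigma_map}[signal]

    def to_dict(self) -> dict[str, float]:
        return {"sigma_bv": self.sigma_bv, "sigma_co": self.sigma_co, "sigma_map": self.sigma_map}


@dataclass(frozen=True)
class MeasurementSet:
    """Per-signal sample times and values with a fitted-signal mask."""

    times: Mapping[str, np.ndarray]
    values: Mapping[str, np.ndarray]
    mask: frozenset[str] = frozenset(SIGNALS)

    def __post_init__(self) -> None:
        times = {s: np.asarray(t, dtype=float) for s, t in self.times.items()}
        values = {s: np.asarray(v, dtype=float) for s, v in self.values.items()}
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", frozenset(self.mask))
        for s in self.mask:
            if s not in SIGNALS:
                raise ValueError(f"unknown signal in mask: {s!r}")
            if s not in times:
                raise ValueError(f"masked signal {s!r} has no samples")
        for s, t in times.items():
            if s not in SIGNALS:
                raise ValueError(f"unknown signal: {s!r}")
            v = values.get(s)
            if v is None or len(v) != len(t):
                raise ValueError(f"times/values length mismatch for {s!r}")
            if len(t) and np.any(np.diff(t) <= 0):
                raise ValueError(f"sample times for {s!r} must be strictly increasing")

    def count(self, signal: str) -> int:
        return len(self.times.get(signal, ()))

    @property
    def n_total_masked(self) -> int:
        return sum(self.count(s) for s in self.mask)

    def withheld(self) -> frozenset[str]:
        """Signals present in the container but excluded from fitting."""
        return frozenset(s for s in self.times if s not in self.mask)

    def with_mask(self, mask) -> "MeasurementSet":
        return replace(self, mask=frozenset(mask))

    def with_case(self, case: int) -> "MeasurementSet":
        return self.with_mask(CASE_MASKS[case])

    @property
    def all_times(self) -> np.ndarray:
        """Union of sample times across all stored signals (sorted)."""
        if not self.times:
            return np.array([])
        return np.unique(np.concatenate([t for t in self.times.values()]))

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        t = self.all_times
        data = {"time_min": t}
        for s in SIGNALS:
            if s in self.times:
                col = np.full(len(t), np.nan)
                col[np.searchsorted(t, self.times[s])] = self.values[s]
                data[_CSV_COLUMNS[s]] = col
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mask=frozenset(SIGNALS)) -> "MeasurementSet":
        if "time_min" not in frame.columns:
            raise ValueError("measurement table must have a time_min column")
        times, values = {}, {}
        for s, col in _CSV_COLUMNS.items():
            if col in frame.columns:
                keep = frame[col].notna().to_numpy()
                times[s] = frame["time_min"].to_numpy(dtype=float)[keep]
                values[s] = frame[col].to_numpy(dtype=float)[keep]
        return cls(times, values, frozenset(mask))

    @classmethod
    def from_csv(cls, path, mask=frozenset(SIGNALS)) -> "MeasurementSet":
        return cls.from_frame(pd.read_csv(path), mask=mask)


@dataclass(frozen=True)
class SubjectRecord:
    """Everything needed to fit one subject: data, baseline, inputs."""

    measurements: MeasurementSet
    context: SubjectContext
    schedule: InputSchedule
    subject_id: str = "subject"

    def with_case(self, case: int) -> "SubjectRecord":
        return replace(self, measurements=self.measurements.with_case(case))
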