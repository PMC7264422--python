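"""Virtual sheep cohorts: protocol, inter-individual variability, noise.

The generator emulates the study conditions the analysis assumes: N = 23
sheep-sized subjects undergoing a 25 ml/kg hemorrhage over minutes 0-15,
5 ml/kg bleeds over 50-55 and 70-75, and closed-loop MAP-targeted fluid
resuscitation over 30-180 min, with BV/CO/MAP sampled every 5 min.

Inter-individual variability instantiates the sparse-deviation (parameter
compressibility) premise of the estimation method: each subject's true
parameter vector is the population mode plus Laplace-distributed deviations
on a random subset of parameters (default: each parameter deviates with
probability 0.3, Laplace scale 0.15 of its physiological range), clipped to
the bounds.  Baseline covariates are drawn to match the calibrated
population summary (BV 2.37 (0.44) L at rest); baseline CO and MAP are the
model's own resting equilibrium at the drawn parameters, so every virtual
subject starts exactly on its model equilibrium.

The original closed-loop resuscitation controllers are not part of this
package's scope; a proportional-integral law with a 70 mmHg set point and a
2 ml/kg/min rate cap stands in (only the existence of MAP-targeted
resuscitation matters to the analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._fastsim import simulate_fast
from .measurements import SIGNALS, MeasurementSet, NoiseModel, SubjectRecord
from .model import (
    PhysiologicalInfeasibilityError,
    SimulationResult,
    SubjectContext,
    baseline_equilibrium,
)
from .parameters import (
    ModelParameters,
    ParameterBounds,
    default_bounds,
    default_population_mode,
)
from .schedule import InputSchedule, Segment

__all__ = [
    "ProtocolSpec",
    "ControllerConfig",
    "GeneratorConfig",
    "VirtualSubject",
    "build_protocol",
    "sample_subject",
    "resuscitation_controller",
    "PIController",
    "generate_population",
    "load_population",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Experimental protocol: hemorrhage doses, windows, sampling grid."""

    initial_hemorrhage_ml_per_kg: float = 25.0
    initial_window: tuple[float, float] = (0.0, 15.0)
    minor_hemorrhage_ml_per_kg: float = 5.0
    minor_windows: tuple[tuple[float, float], ...] = ((50.0, 55.0), (70.0, 75.0))
    resuscitation_window: tuple[float, float] = (30.0, 180.0)
    sampling_interval: float = 5.0
    horizon: float = 180.0

    def __post_init__(self) -> None:
        windows = [self.initial_window, *self.minor_windows]
        for lo, hi in windows:
            if not (0.0 <= lo < hi <= self.horizon):
                raise ValueError(f"hemorrhage window [{lo}, {hi}] outside [0, {self.horizon}]")
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("hemorrhage windows overlap")
        if self.initial_hemorrhage_ml_per_kg < 0 or self.minor_hemorrhage_ml_per_kg < 0:
            raise ValueError("doses must be non-negative")
        lo, hi = self.resuscitation_window
        if not (0.0 <= lo < hi <= self.horizon):
            raise ValueError("resuscitation window outside the horizon")

    @property
    def sampling_grid(self) -> np.ndarray:
        return np.arange(0.0, self.horizon + 0.5 * self.sampling_interval, self.sampling_interval)


@dataclass(frozen=True)
class ControllerConfig:
    """PI resuscitation-controller settings (per-kg gains and rate cap)."""

    map_setpoint: float = 70.0
    u_max_ml_per_kg_min: float = 2.0
    kp_ml_per_kg_min_per_mmHg: float = 0.04
    ki_ml_per_kg_min_per_mmHg_min: float = 0.008


@dataclass(frozen=True)
class GeneratorConfig:
    """Virtual-population settings (see module docstring for rationale)."""

    theta_mode: ModelParameters = field(default_factory=default_population_mode)
    bounds: ParameterBounds = field(default_factory=default_bounds)
    deviation_scale: float = 0.15  # Laplace scale as fraction of b_m
    sparsity: float = 0.3  # probability a parameter deviates in a subject
    vb0_mean: float = 2.37  # L, baseline blood volume
    vb0_sd: float = 0.44
    vb0_min: float = 0.9
    co0_mean: float = 4.40  # L/min, baseline cardiac output (anchored)
    co0_sd: float = 0.96
    co0_min: float = 2.0
    anchor_co0: bool = True
    hr_mean: float = 90.0  # bpm
    hr_sd: float = 8.0
    hr_min: float = 50.0
    weight_range: tuple[float, float] = (35.0, 50.0)  # kg
    noise: NoiseModel = field(default_factory=NoiseModel)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    sim_step: float = 0.1  # min, RK4 step for generation
    retry_cap: int = 50

    def __post_init__(self) -> None:
        if self.deviation_scale <= 0:
            raise ValueError("deviation_scale must be > 0")
        if not (0.0 <= self.sparsity <= 1.0):
            raise ValueError("sparsity must lie in [0, 1]")
        if not self.bounds.contains(self.theta_mode):
            raise ValueError("theta_mode must lie within bounds")


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated animal: truth, realized inputs, and noisy data."""

    subject_id: str
    theta_true: ModelParameters
    context: SubjectContext
    schedule: InputSchedule
    truth: SimulationResult
    measurements: MeasurementSet
    sim_step: float

    @property
    def record(self) -> SubjectRecord:
        return SubjectRecord(self.measurements, self.context, self.schedule, self.subject_id)


# ---------------------------------------------------------------------------
# Protocol construction


def build_protocol(
    spec: ProtocolSpec,
    body_weight: float,
    infusion_segments: Sequence[Segment] | None = None,
) -> InputSchedule:
    """Hemorrhage schedule scaled by body weight, with optional infusions.

    Each dose (ml/kg) is spread uniformly over its window; e.g. 25 ml/kg at
    40 kg is 1.0 L over 0-15 min (66.7 ml/min).
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    segments: list[Segment] = []
    total = spec.initial_hemorrhage_ml_per_kg * body_weight / 1000.0  # L
    lo, hi = spec.initial_window
    if total > 0:
        segments.append(Segment(lo, hi, 0.0, total / (hi - lo)))
    minor = spec.minor_hemorrhage_ml_per_kg * body_weight / 1000.0
    for lo, hi in spec.minor_windows:
        if minor > 0:
            segments.append(Segment(lo, hi, 0.0, minor / (hi - lo)))
    sched = InputSchedule(segments, horizon=spec.horizon)
    if infusion_segments:
        sched = sched.with_segments(list(infusion_segments))
    return sched


# ---------------------------------------------------------------------------
# Subject sampling


def _sample_theta(config: GeneratorConfig, rng: np.random.Generator) -> ModelParameters:
    base = config.theta_mode.to_array()
    b = config.bounds.ranges
    deviates = rng.random(len(base)) < config.sparsity
    dev = rng.laplace(0.0, config.deviation_scale * b)
    arr = config.bounds.clip(base + np.where(deviates, dev, 0.0))
    return ModelParameters.from_array(arr)


def sample_subject(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[ModelParameters, SubjectContext]:
    """Draw (theta_true, context); baseline CO/MAP are the model equilibrium.

    Draws that yield an infeasible resting equilibrium are resampled up to
    ``config.retry_cap`` times.
    """
    lo_w, hi_w = config.weight_range
    for _ in range(config.retry_cap):
        theta = _sample_theta(config, rng)
        vb0 = rng.normal(config.vb0_mean, config.vb0_sd)
        co0_target = rng.normal(config.co0_mean, config.co0_sd)
        hr = rng.normal(config.hr_mean, config.hr_sd)
        weight = rng.uniform(lo_w, hi_w)
        if vb0 < config.vb0_min or hr < config.hr_min or co0_target < config.co0_min:
            continue
        if config.anchor_co0:
            # anchor: rescale A so the resting equilibrium CO equals the
            # drawn baseline CO (inter-individual CO variation = A variation)
            arg = (
                1.0
                + theta.g_over_BCs * (1.0 - theta.eta) * vb0
                - theta.gk_over_B * theta.MAP_target
            )
            if arg <= 1.0:
                continue
            a_req = hr * (np.log(arg) - theta.A_over_Es * theta.MAP_target) / co0_target
            if a_req <= 0:
                continue
            lo_a, hi_a = config.bounds.lower[3], config.bounds.upper[3]
            theta = theta.replace(A=float(np.clip(a_req, lo_a, hi_a)))
        try:
            co0, map0 = baseline_equilibrium(theta, vb0, hr)
        except PhysiologicalInfeasibilityError:
            continue
        if co0 < 0.5:  # exclude non-viable resting states
            continue
        context = SubjectContext(V_B0=vb0, CO_0=co0, MAP_0=map0, body_weight=weight, HR=hr)
        return theta, context
    raise RuntimeError(f"no feasible subject draw within {config.retry_cap} attempts")


# ---------------------------------------------------------------------------
# Resuscitation controller


@dataclass
class PIController:
    """Clamped PI law on the MAP error, with integral anti-windup."""

    config: ControllerConfig
    body_weight: float
    integral: float = 0.0

    @property
    def u_max(self) -> float:
        return self.config.u_max_ml_per_kg_min * self.body_weight / 1000.0

    def rate(self, map_measured: float) -> float:
        """Infusion rate (L/min) for the coming hold interval."""
        err = self.config.map_setpoint - map_measured
        kp = self.config.kp_ml_per_kg_min_per_mmHg * self.body_weight / 1000.0
        ki = self.config.ki_ml_per_kg_min_per_mmHg_min * self.body_weight / 1000.0
        u = kp * err + ki * self.integral
        return float(np.clip(u, 0.0, self.u_max))

    def update(self, map_measured: float, dt: float) -> None:
        err = self.config.map_setpoint - map_measured
        ki = self.config.ki_ml_per_kg_min_per_mmHg_min * self.body_weight / 1000.0
        nxt = self.integral + err * dt
        if ki > 0:
            cap = self.u_max / ki  # anti-windup: ki * integral never exceeds u_max
            nxt = float(np.clip(nxt, -cap, cap))
        self.integral = nxt


def resuscitation_controller(
    map_measured: float,
    config: ControllerConfig,
    body_weight: float,
    integral: float = 0.0,
) -> float:
    """Stateless wrapper: PI infusion rate (L/min) given the integral state."""
    return PIController(config, body_weight, integral).rate(map_measured)


# ---------------------------------------------------------------------------
# Population generation


def _closed_loop_schedule(
    theta: ModelParameters,
    context: SubjectContext,
    config: GeneratorConfig,
    protocol: ProtocolSpec,
    rng: np.random.Generator,
) -> InputSchedule:
    """Realize the infusion schedule by running the PI loop at 5-min instants.

    The controller sees the noisy MAP (its own measurement noise draws); the
    realized piecewise-constant infusion segments are then frozen into the
    subject's schedule.
    """
    hem = build_protocol(protocol, context.body_weight)
    lo, hi = protocol.resuscitation_window
    dt = protocol.sampling_interval
    ctrl = PIController(config.controller, context.body_weight)
    infusion: list[Segment] = []
    t = lo
    while t < hi - 1e-9:
        sched = hem if not infusion else build_protocol(protocol, context.body_weight, infusion)
        grid = np.array([0.0, t]) if t > 0 else np.array([0.0])
        res = simulate_fast(theta, context, sched, grid, step=config.sim_step)
        map_true = float(res.map[-1])
        map_meas = map_true + rng.normal(0.0, config.noise.sigma_map)
        u = ctrl.rate(map_meas)
        ctrl.update(map_meas, dt)
        t_next = min(t + dt, hi)
        if u > 0:
            infusion.append(Segment(t, t_next, u, 0.0))
        t = t_next
    return build_protocol(protocol, context.body_weight, infusion)


def _measure(
    truth: SimulationResult, noise: NoiseModel, rng: np.random.Generator
) -> MeasurementSet:
    times = {s: truth.time.copy() for s in SIGNALS}
    values = {
        s: truth.signal(s) + rng.normal(0.0, noise.sigma(s), size=len(truth.time))
        for s in SIGNALS
    }
    return MeasurementSet(times, values)


def generate_population(
    config: GeneratorConfig,
    n: int = 23,
    protocol: ProtocolSpec | None = None,
    seed: int | np.random.Generator = 0,
    out_dir: str | Path | None = None,
) -> list[VirtualSubject]:
    """Generate ``n`` virtual subjects; optionally write the dataset to disk.

    Reproducible: a fixed seed yields byte-identical datasets.  Each subject
    carries its noise-free trajectories (from a single full-pass fixed-step
    simulation of the realized schedule) and noisy measurements on the
    protocol sampling grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    protocol = protocol or ProtocolSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects: list[VirtualSubject] = []
    for i in range(n):
        # a draw that collapses under the protocol (no admissible CO) is
        # resampled; the retry cap bounds the rejection loop
        for attempt in range(config.retry_cap):
            theta, context = sample_subject(config, rng)
            try:
                schedule = _closed_loop_schedule(theta, context, config, protocol, rng)
                truth = simulate_fast(
                    theta, context, schedule, protocol.sampling_grid, step=config.sim_step
                )
                break
            except PhysiologicalInfeasibilityError:
                continue
        else:
            raise RuntimeError(
                f"subject {i}: no protocol-feasible draw within {config.retry_cap} attempts"
            )
        measurements = _measure(truth, config.noise, rng)
        subjects.append(
            VirtualSubject(
                subject_id=f"s{i:02d}",
                theta_true=theta,
                context=context,
                schedule=schedule,
                truth=truth,
                measurements=measurements,
                sim_step=config.sim_step,
            )
        )
    if out_dir is not None:
        write_population(subjects, out_dir, config)
    return subjects


def write_population(
    subjects: Sequence[VirtualSubject], out_dir: str | Path, config: GeneratorConfig
) -> None:
    """Write one measurement CSV, schedule CSV and truth JSON per subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_subjects": len(subjects),
        "noise": config.noise.to_dict(),
        "subjects": [],
    }
    for s in subjects:
        s.measurements.to_csv(out / f"{s.subject_id}_measurements.csv")
        s.schedule.to_csv(out / f"{s.subject_id}_schedule.csv")
        sidecar = {
            "subject_id": s.subject_id,
            "theta_true": s.theta_true.to_dict(),
            "context": s.context.to_dict(),
            "sim_step": s.sim_step,
            "horizon": s.schedule.horizon,
        }
        (out / f"{s.subject_id}_truth.json").write_text(json.dumps(sidecar, indent=1))
        manifest["subjects"].append(s.subject_id)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_population(data_dir: str | Path) -> list[SubjectRecord]:
    """Load a written dataset back as fit-ready subject records."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    records = []
    for sid in manifest["subjects"]:
        ms = MeasurementSet.from_csv(data_dir / f"{sid}_measurements.csv")
        sidecar = json.loads((data_dir / f"{sid}_truth.json").read_text())
        context = SubjectContext.from_mapping(sidecar["context"])
        schedule = InputSchedule.from_csv(
            data_dir / f"{sid}_schedule.csv", horizon=sidecar.get("horizon")
        )
        records.append(SubjectRecord(ms, context, schedule, sid))
    return records
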