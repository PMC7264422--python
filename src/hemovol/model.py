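"""Forward model: blood-volume kinetics, implicit cardiac output, MAP regulation.

State variables (all deviations from the pre-protocol baseline):

* ``dVB``  — change in blood volume ΔV_B (L), obeying
  dΔV_B/dt = u(t) − v(t) − u_ex(t), where u and v are the external fluid
  gain/loss rates and u_ex = −K_p (r_BV − ΔV_B) is the blood/interstitium
  exchange rate steering ΔV_B toward the target
  r_BV = ∫u/(1+α_u) − ∫v/(1+α_v).
* ``dTPR`` — change in total peripheral resistance ΔTPR (mmHg·min/L), driven
  by the short-term pressure-regulation law
  dΔTPR/dt = −p_TPR ΔTPR + k_TPR (MAP_target − MAP).
* ``cum_u``, ``cum_v`` — running input integrals (L), exact because the
  schedules are piecewise constant.

Cardiac output is an algebraic (implicit) function of the state: the unique
CO > 0 with

    CO = HR / (A + (A/E_s) HR TPR) · log(1 − (γk/B) TPR CO
                                         + (γ/(B C_s)) (V_B − η V_B0)),

whose right-hand side is strictly decreasing in CO whenever TPR > 0, so the
root is unique and bracketable.  MAP = CO · TPR with TPR = TPR_0 + ΔTPR and
TPR_0 = MAP_0 / CO_0.

The reference integrator is an adaptive stiff-capable solver (LSODA,
rtol 1e-8 / atol 1e-10) restarted at every schedule breakpoint so that the
discontinuous input rates never cross an adaptive step.  A fast fixed-step
path used by the estimators lives in :mod:`hemovol._fastsim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import ModelParameters
from .schedule import InputSchedule

__all__ = [
    "PhysiologicalInfeasibilityError",
    "SubjectContext",
    "SimulationResult",
    "target_blood_volume",
    "fluid_exchange_rate",
    "solve_cardiac_output",
    "baseline_equilibrium",
    "state_derivatives",
    "simulate_subject",
]

CO_EPS = 1e-9  # lower bracket for the implicit CO solve, L/min
CO_SOLVE_TOL = 1e-12


class PhysiologicalInfeasibilityError(RuntimeError):
    """The implicit CO equation has no admissible solution at this state."""

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}


@dataclass(frozen=True)
class SubjectContext:
    """Per-subject baseline state and covariates.

    ``TPR_0`` is always the derived ratio MAP_0 / CO_0.  Heart rate defaults
    to a constant but may be any positive function of time (min -> bpm).
    """

    V_B0: float
    CO_0: float
    MAP_0: float
    body_weight: float
    HR: float = 90.0
    hr_signal: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for name in ("V_B0", "CO_0", "MAP_0", "body_weight", "HR"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val}")

    @property
    def TPR_0(self) -> float:
        return self.MAP_0 / self.CO_0

    def heart_rate(self, t: float) -> float:
        return float(self.hr_signal(t)) if self.hr_signal is not None else self.HR

    def to_dict(self) -> dict[str, float]:
        return {
            "V_B0": self.V_B0,
            "CO_0": self.CO_0,
            "MAP_0": self.MAP_0,
            "body_weight": self.body_weight,
            "HR": self.HR,
        }

    @classmethod
    def from_mapping(cls, m) -> "SubjectContext":
        return cls(
            V_B0=float(m["V_B0"]),
            CO_0=float(m["CO_0"]),
            MAP_0=float(m["MAP_0"]),
            body_weight=float(m["body_weight"]),
            HR=float(m.get("HR", 90.0)),
        )


# ---------------------------------------------------------------------------
# Algebraic pieces


def target_blood_volume(cum_u: float, cum_v: float, alpha_u: float, alpha_v: float) -> float:
    """Target blood-volume change r_BV = cum_u/(1+α_u) − cum_v/(1+α_v), L.

    1/(1+α_u) is the fraction of gained fluid that stays intravascular;
    1/(1+α_v) the fraction of lost volume not refilled from the interstitium.
    """
    if not np.all(np.isfinite([cum_u, cum_v, alpha_u, alpha_v])):
        raise ValueError("non-finite input to target_blood_volume")
    if cum_u < 0 or cum_v < 0:
        raise ValueError("cumulative inputs must be >= 0")
    if alpha_u <= -1 or alpha_v <= -1:
        raise ValueError("alpha_u and alpha_v must exceed -1")
    return cum_u / (1.0 + alpha_u) - cum_v / (1.0 + alpha_v)


def fluid_exchange_rate(r_bv: float, d_vb: float, k_p: float) -> float:
    """Blood/interstitium exchange rate u_ex = −K_p (r_BV − ΔV_B), L/min.

    u_ex enters the volume balance with a minus sign, so negative u_ex moves
    ΔV_B toward the target r_BV.
    """
    if not np.all(np.isfinite([r_bv, d_vb, k_p])):
        raise ValueError("non-finite input to fluid_exchange_rate")
    if k_p <= 0:
        raise ValueError(f"K_p must be > 0, got {k_p}")
    return -k_p * (r_bv - d_vb)


def solve_cardiac_output(
    params: ModelParameters,
    hr: float,
    tpr: float,
    v_b: float,
    v_b0: float,
    tol: float = CO_SOLVE_TOL,
) -> float:
    """Solve the implicit CO equilibrium equation for the unique CO > 0.

    Uses a bracketed Brent solve on (ε, CO_max) where CO_max is the largest
    CO keeping the log argument positive.  Raises
    :class:`PhysiologicalInfeasibilityError` when no admissible root exists.
    """
    if hr <= 0 or tpr <= 0:
        raise PhysiologicalInfeasibilityError(
            f"HR and TPR must be > 0 (HR={hr}, TPR={tpr})",
            {"HR": hr, "TPR": tpr},
        )
    c1 = hr / (params.A + params.A_over_Es * hr * tpr)
    base = params.g_over_BCs * (v_b - params.eta * v_b0) + 1.0
    slope = params.gk_over_B * tpr
    state = {"HR": hr, "TPR": tpr, "V_B": v_b, "V_B0": v_b0, "log_base": base}
    if base <= 0:
        raise PhysiologicalInfeasibilityError(
            f"log argument non-positive for all CO (base={base:.3g})", state
        )

    def f(co: float) -> float:
        return c1 * np.log(base - slope * co) - co

    co_max = base / slope * (1.0 - 1e-13) if slope > 0 else np.inf
    lo = CO_EPS
    if f(lo) <= 0:
        # root at or below epsilon flow: physiologically a circulatory collapse
        raise PhysiologicalInfeasibilityError(
            "implicit CO equation has no positive root (collapse)", state
        )
    if np.isfinite(co_max):
        hi = co_max
    else:
        hi = max(2.0 * c1 * np.log(base), 1.0)
        while f(hi) > 0:
            hi *= 2.0
    if f(hi) > 0:
        raise PhysiologicalInfeasibilityError("no sign change in CO bracket", state)
    co = brentq(f, lo, hi, xtol=tol, rtol=8.882e-16)
    return float(co)


def co_residual(params: ModelParameters, co: float, hr: float, tpr: float, v_b: float, v_b0: float) -> float:
    """|CO − RHS(CO)| of the implicit equilibrium equation."""
    c1 = hr / (params.A + params.A_over_Es * hr * tpr)
    arg = params.g_over_BCs * (v_b - params.eta * v_b0) + 1.0 - params.gk_over_B * tpr * co
    if arg <= 0:
        return np.inf
    return abs(c1 * np.log(arg) - co)


def baseline_equilibrium(params: ModelParameters, v_b0: float, hr: float) -> tuple[float, float]:
    """Closed-form (CO_0, MAP_0) of the resting equilibrium.

    At rest ΔTPR = 0 requires MAP = MAP_target, so TPR·CO = MAP_target and
    the log argument is the constant
    L0 = log(1 + (γ/(B C_s))(1−η) V_B0 − (γk/B) MAP_target), giving

        CO_0 = HR (L0 − (A/E_s) MAP_target) / A.
    """
    arg = 1.0 + params.g_over_BCs * (1.0 - params.eta) * v_b0 - params.gk_over_B * params.MAP_target
    if arg <= 0:
        raise PhysiologicalInfeasibilityError(
            f"baseline log argument non-positive ({arg:.3g})", {"V_B0": v_b0}
        )
    co0 = hr * (np.log(arg) - params.A_over_Es * params.MAP_target) / params.A
    if co0 <= 0:
        raise PhysiologicalInfeasibilityError(
            f"baseline equilibrium CO non-positive ({co0:.3g})", {"V_B0": v_b0}
        )
    return float(co0), float(params.MAP_target)


# ---------------------------------------------------------------------------
# Dynamics


def state_derivatives(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    context: SubjectContext,
    schedule: InputSchedule,
) -> np.ndarray:
    """Time derivatives of (ΔV_B, ΔTPR, cum_u, cum_v) at time t."""
    d_vb, d_tpr, cum_u, cum_v = state
    u, v = schedule.rates(t)
    r_bv = target_blood_volume(max(cum_u, 0.0), max(cum_v, 0.0), params.alpha_u, params.alpha_v)
    u_ex = fluid_exchange_rate(r_bv, d_vb, params.K_p)
    tpr = context.TPR_0 + d_tpr
    co = solve_cardiac_output(params, context.heart_rate(t), tpr, context.V_B0 + d_vb, context.V_B0)
    map_ = co * tpr
    return np.array(
        [
            u - v - u_ex,
            -params.p_TPR * d_tpr + params.k_TPR * (params.MAP_target - map_),
            u,
            v,
        ]
    )


@dataclass
class SimulationResult:
    """Trajectories on a sampling grid plus solver diagnostics."""

    time: np.ndarray
    delta_vb: np.ndarray
    vb: np.ndarray
    co: np.ndarray
    map: np.ndarray
    tpr: np.ndarray
    r_bv: np.ndarray
    u_ex: np.ndarray
    max_co_residual: float = 0.0
    nfev: int = 0
    method: str = "adaptive"

    def signal(self, name: str) -> np.ndarray:
        return {"bv": self.vb, "co": self.co, "map": self.map}[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "BV_L": self.vb,
                "CO_L_per_min": self.co,
                "MAP_mmHg": self.map,
                "TPR": self.tpr,
                "r_BV_L": self.r_bv,
                "u_ex_L_per_min": self.u_ex,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _outputs_at(
    params: ModelParameters,
    context: SubjectContext,
    schedule: InputSchedule,
    t: float,
    d_vb: float,
    d_tpr: float,
) -> tuple[float, float, float, float, float, float]:
    cum_u, cum_v = schedule.cumulative(t)
    r_bv = target_blood_volume(cum_u, cum_v, params.alpha_u, params.alpha_v)
    u_ex = fluid_exchange_rate(r_bv, d_vb, params.K_p)
    tpr = context.TPR_0 + d_tpr
    v_b = context.V_B0 + d_vb
    co = solve_cardiac_output(params, context.heart_rate(t), tpr, v_b, context.V_B0)
    resid = co_residual(params, co, context.heart_rate(t), tpr, v_b, context.V_B0)
    return v_b, co, co * tpr, tpr, r_bv, u_ex, resid


def simulate_subject(
    params: ModelParameters,
    context: SubjectContext,
    schedule: InputSchedule,
    time_grid: np.ndarray,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    step: float = 0.25,
) -> SimulationResult:
    """Simulate a subject's BV/CO/MAP response on ``time_grid``.

    ``method="adaptive"`` integrates with LSODA restarted at every schedule
    breakpoint; ``method="fast"`` delegates to the fixed-step RK4 core used
    inside the estimators (step size ``step`` minutes).
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) == 0 or np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be a non-empty strictly increasing 1-D array")
    if time_grid[0] < 0 or time_grid[-1] > schedule.horizon + 1e-9:
        raise ValueError("time_grid must lie within [0, schedule.horizon]")

    if method == "fast":
        from ._fastsim import simulate_fast

        return simulate_fast(params, context, schedule, time_grid, step=step)
    if method != "adaptive":
        raise ValueError(f"unknown method {method!r}")

    # integration checkpoints: schedule breakpoints + requested samples
    checkpoints = np.unique(np.concatenate([schedule.breakpoints, time_grid, [0.0]]))
    checkpoints = checkpoints[(checkpoints >= 0) & (checkpoints <= time_grid[-1] + 1e-12)]
    state = np.zeros(4)
    nfev = 0
    samples: dict[float, tuple[float, float]] = {}
    grid_set = set(np.round(time_grid, 9))
    if np.round(checkpoints[0], 9) in grid_set:
        samples[checkpoints[0]] = (state[0], state[1])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return state_derivatives(t, y, params, context, schedule)

    for a, b in zip(checkpoints[:-1], checkpoints[1:]):
        if b - a < 1e-12:
            continue
        # evaluate rates at segment interior so the discontinuity at `a` is
        # resolved consistently within this restart
        sol = solve_ivp(
            rhs, (a, b), state, method="LSODA", rtol=rtol, atol=atol, dense_output=False
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a:.4g}, {b:.4g}]: {sol.message}")
        nfev += sol.nfev
        state = sol.y[:, -1]
        if np.round(b, 9) in grid_set:
            samples[b] = (state[0], state[1])

    rows = []
    max_resid = 0.0
    for t in time_grid:
        d_vb, d_tpr = samples[float(t)] if float(t) in samples else samples[min(samples, key=lambda s: abs(s - t))]
        v_b, co, map_, tpr, r_bv, u_ex, resid = _outputs_at(params, context, schedule, t, d_vb, d_tpr)
        max_resid = max(max_resid, resid)
        rows.append((d_vb, v_b, co, map_, tpr, r_bv, u_ex))
    arr = np.array(rows)
    return SimulationResult(
        time=time_grid,
        delta_vb=arr[:, 0],
        vb=arr[:, 1],
        co=arr[:, 2],
        map=arr[:, 3],
        tpr=arr[:, 4],
        r_bv=arr[:, 5],
        u_ex=arr[:, 6],
        max_co_residual=max_resid,
        nfev=nfev,
        method="adaptive",
    )
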