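"""Fixed-step RK4 integration core (numba-jitted) for the forward model.

This is the workhorse behind the estimators: a fit evaluates the forward
model hundreds of times, so the right-hand side (including the implicit
cardiac-output solve) is compiled with numba.  The step sequence is aligned
to the schedule breakpoints and the sampling grid, so piecewise-constant
inputs never straddle a step and re-simulating a stored schedule reproduces
trajectories bit-for-bit.

The implicit CO equation CO = c1·log(base − slope·CO) is solved per stage by
a safeguarded Newton iteration (bracketed, warm-started from the previous
stage's CO); the bracket plus monotonicity of the right-hand side guarantee
convergence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import PhysiologicalInfeasibilityError, SimulationResult, SubjectContext
from .parameters import ModelParameters
from .schedule import InputSchedule

__all__ = ["simulate_fast"]

_CO_EPS = 1e-12


@njit(cache=True)
def _co_solve(c1, base, slope, guess):  # pragma: no cover - jitted
    """Root of f(co) = c1*log(base - slope*co) - co on (0, co_max).

    Returns -1.0 when no admissible root exists (circulatory collapse or a
    non-positive log argument over the whole interval).
    """
    if base <= 0.0 or c1 <= 0.0:
        return -1.0
    f0 = c1 * np.log(base)
    if f0 <= _CO_EPS:
        return -1.0
    lo = 0.0
    if slope > 0.0:
        hi = base / slope * (1.0 - 1e-12)
        if c1 * np.log(base - slope * hi) - hi > 0.0:
            return -1.0
    else:
        hi = 2.0 * f0
        while c1 * np.log(base - slope * hi) - hi > 0.0:
            hi *= 2.0
    co = guess
    if co <= lo or co >= hi:
        co = 0.5 * (lo + hi)
    for _ in range(100):
        arg = base - slope * co
        if arg <= 0.0:
            co = 0.5 * (lo + hi)
            continue
        f = c1 * np.log(arg) - co
        if f > 0.0:
            lo = co
        else:
            hi = co
        fp = -c1 * slope / arg - 1.0
        step = f / fp
        nxt = co - step
        if nxt <= lo or nxt >= hi:
            nxt = 0.5 * (lo + hi)
        if abs(nxt - co) < 1e-14 * (1.0 + co):
            co = nxt
            break
        co = nxt
    return co


@njit(cache=True)
def _rk4_run(
    theta,
    hr,
    tpr0,
    vb0,
    edges,
    u_rates,
    v_rates,
    cumu_edges,
    cumv_edges,
    is_output,
    step,
    out_dvb,
    out_dtpr,
    out_co,
    out_tpr,
):  # pragma: no cover - jitted
    """Integrate over the merged edge partition; fill outputs at flagged edges.

    Returns (status, t_fail): status 0 = ok, 1 = infeasible CO solve.
    """
    alpha_u = theta[0]
    alpha_v = theta[1]
    k_p = theta[2]
    a_const = theta[3]
    a_over_es = theta[4]
    gk_over_b = theta[5]
    g_over_bcs = theta[6]
    eta = theta[7]
    k_tpr = theta[8]
    p_tpr = theta[9]
    map_target = theta[10]

    d_vb = 0.0
    d_tpr = 0.0
    co_warm = 1.0
    n_out = 0

    if is_output[0]:
        tpr = tpr0 + d_tpr
        co = _co_solve(
            hr / (a_const + a_over_es * hr * tpr),
            g_over_bcs * (vb0 + d_vb - eta * vb0) + 1.0,
            gk_over_b * tpr,
            co_warm,
        )
        if co <= 0.0:
            return 1, edges[0]
        co_warm = co
        out_dvb[n_out] = d_vb
        out_dtpr[n_out] = d_tpr
        out_co[n_out] = co
        out_tpr[n_out] = tpr
        n_out += 1

    for k in range(len(u_rates)):
        t0 = edges[k]
        t1 = edges[k + 1]
        span = t1 - t0
        nsub = int(np.ceil(span / step))
        if nsub < 1:
            nsub = 1
        h = span / nsub
        u = u_rates[k]
        v = v_rates[k]
        net = u - v
        inv_u = 1.0 / (1.0 + alpha_u)
        inv_v = 1.0 / (1.0 + alpha_v)
        for j in range(nsub):
            t = t0 + j * h
            # RK4 stages; cumulative inputs are exact linear functions of t
            y1 = d_vb
            z1 = d_tpr
            ok = True
            k1v = 0.0
            k1z = 0.0
            k2v = 0.0
            k2z = 0.0
            k3v = 0.0
            k3z = 0.0
            k4v = 0.0
            k4z = 0.0
            for stage in range(4):
                if stage == 0:
                    ts = t
                    yv = y1
                    yz = z1
                elif stage == 1:
                    ts = t + 0.5 * h
                    yv = y1 + 0.5 * h * k1v
                    yz = z1 + 0.5 * h * k1z
                elif stage == 2:
                    ts = t + 0.5 * h
                    yv = y1 + 0.5 * h * k2v
                    yz = z1 + 0.5 * h * k2z
                else:
                    ts = t + h
                    yv = y1 + h * k3v
                    yz = z1 + h * k3z
                cumu = cumu_edges[k] + u * (ts - t0)
                cumv = cumv_edges[k] + v * (ts - t0)
                r_bv = cumu * inv_u - cumv * inv_v
                u_ex = -k_p * (r_bv - yv)
                tpr = tpr0 + yz
                if tpr <= 0.0:
                    ok = False
                    break
                co = _co_solve(
                    hr / (a_const + a_over_es * hr * tpr),
                    g_over_bcs * (vb0 + yv - eta * vb0) + 1.0,
                    gk_over_b * tpr,
                    co_warm,
                )
                if co <= 0.0:
                    ok = False
                    break
                co_warm = co
                dv = net - u_ex
                dz = -p_tpr * yz + k_tpr * (map_target - co * tpr)
                if stage == 0:
                    k1v, k1z = dv, dz
                elif stage == 1:
                    k2v, k2z = dv, dz
                elif stage == 2:
                    k3v, k3z = dv, dz
                else:
                    k4v, k4z = dv, dz
            if not ok:
                return 1, t
            d_vb = y1 + h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            d_tpr = z1 + h / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
        if is_output[k + 1]:
            tpr = tpr0 + d_tpr
            co = _co_solve(
                hr / (a_const + a_over_es * hr * tpr),
                g_over_bcs * (vb0 + d_vb - eta * vb0) + 1.0,
                gk_over_b * tpr,
                co_warm,
            )
            if co <= 0.0:
                return 1, t1
            co_warm = co
            out_dvb[n_out] = d_vb
            out_dtpr[n_out] = d_tpr
            out_co[n_out] = co
            out_tpr[n_out] = tpr
            n_out += 1
    return 0, 0.0


def simulate_fast(
    params: ModelParameters,
    context: SubjectContext,
    schedule: InputSchedule,
    time_grid: np.ndarray,
    step: float = 0.25,
) -> SimulationResult:
    """Fixed-step RK4 simulation on ``time_grid`` (see module docstring)."""
    if context.hr_signal is not None:
        raise ValueError("the fast path supports constant heart rate only")
    time_grid = np.asarray(time_grid, dtype=float)
    t_end = time_grid[-1]

    edges = np.unique(np.concatenate([schedule.breakpoints, time_grid, [0.0]]))
    edges = edges[edges <= t_end + 1e-12]
    k_idx = np.minimum(
        np.searchsorted(schedule.breakpoints, edges[:-1], side="right") - 1,
        len(schedule.u_rates) - 1,
    )
    u_rates = schedule.u_rates[k_idx]
    v_rates = schedule.v_rates[k_idx]
    cumu_edges = np.empty(len(edges) - 1)
    cumv_edges = np.empty(len(edges) - 1)
    for i, t in enumerate(edges[:-1]):
        cumu_edges[i], cumv_edges[i] = schedule.cumulative(float(t))

    grid_rounded = np.round(time_grid, 9)
    is_output = np.isin(np.round(edges, 9), grid_rounded)

    n_out = int(is_output.sum())
    out_dvb = np.empty(n_out)
    out_dtpr = np.empty(n_out)
    out_co = np.empty(n_out)
    out_tpr = np.empty(n_out)

    status, t_fail = _rk4_run(
        params.to_array(),
        float(context.HR),
        context.TPR_0,
        context.V_B0,
        edges,
        u_rates,
        v_rates,
        cumu_edges,
        cumv_edges,
        is_output,
        float(step),
        out_dvb,
        out_dtpr,
        out_co,
        out_tpr,
    )
    if status != 0:
        raise PhysiologicalInfeasibilityError(
            f"implicit CO solve infeasible at t={t_fail:.4g} min",
            {"t": float(t_fail), "params": params.to_dict()},
        )

    r_bv = np.empty(n_out)
    u_ex = np.empty(n_out)
    for i, t in enumerate(time_grid):
        cu, cv = schedule.cumulative(float(t))
        r_bv[i] = cu / (1.0 + params.alpha_u) - cv / (1.0 + params.alpha_v)
        u_ex[i] = -params.K_p * (r_bv[i] - out_dvb[i])

    return SimulationResult(
        time=time_grid,
        delta_vb=out_dvb,
        vb=context.V_B0 + out_dvb,
        co=out_co,
        map=out_co * out_tpr,
        tpr=out_tpr,
        r_bv=r_bv,
        u_ex=u_ex,
        max_co_residual=0.0,
        nfev=0,
        method="fast",
    )
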