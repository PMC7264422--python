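"""Fit costs, population-average fitting, regularized individualization.

The individualization problem is a maximum-a-posteriori point estimate

    theta_hat = argmin_{theta in [lower, upper]}  J1(theta) + J2(theta)

with the covariance-weighted output cost

    J1 = sum_{signals in mask} sum_j (model(t_j) - data(t_j))^2 / sigma_s^2

and the Laplace-prior (L1) penalty

    J2 = lam * sum_m |theta_m - theta_bar_m| / b_m,      b_m = upper_m - lower_m.

lam = 0 is pure maximum likelihood; lam -> infinity collapses the estimate
onto the population mode theta_bar.  The population-average model minimizes
the pooled J1 over L subjects at a shared theta (no penalty).

Optimization is multi-start and bounded, on range-normalized coordinates
(the unit box).  Smooth pure-likelihood problems (the population fit and any
lam = 0 fit) use a trust-region-reflective least-squares solver on the
stacked normalized residual vector; objectives carrying the non-smooth L1
term use Powell, which tolerates the kink.  Starts are the prior mode plus
scrambled-Sobol points.  The regularization weight is selected per subject
at the knee of the (J1, D) trade-off curve traced over a warm-started
lambda sweep, where D = J2/lam is the range-normalized L1 deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from ._fastsim import simulate_fast
from .measurements import MeasurementSet, NoiseModel, SubjectRecord
from .model import PhysiologicalInfeasibilityError, SubjectContext, simulate_subject
from .parameters import ModelParameters, ParameterBounds, Prior, default_bounds
from .schedule import InputSchedule

__all__ = [
    "INFEASIBLE_PENALTY",
    "FitResult",
    "LambdaSweep",
    "PopulationModel",
    "IndividualizedModel",
    "cost_j1",
    "regularizer_j2",
    "fit_population",
    "individualize",
    "sweep_lambda",
    "select_lambda",
    "default_lambda_grid",
]

#: J1 stand-in when the model is not simulable at theta, so bounded searches
#: can retreat instead of aborting.
INFEASIBLE_PENALTY = 1e12


def default_lambda_grid(lam_max: float = 10.0, n: int = 25) -> np.ndarray:
    """{0} followed by n log-spaced weights in [1e-3, lam_max]."""
    return np.concatenate([[0.0], np.logspace(-3, np.log10(lam_max), n)])


# ---------------------------------------------------------------------------
# Costs


def _predict_signals(
    theta: ModelParameters,
    measurements: MeasurementSet,
    context: SubjectContext,
    schedule: InputSchedule,
    signals: Sequence[str],
    sim_step: float = 0.25,
    method: str = "fast",
) -> dict[str, np.ndarray]:
    """Model output sampled at each signal's measurement times."""
    grid = measurements.all_times
    if len(grid) == 0:
        raise ValueError("measurement set has no sample times")
    res = simulate_subject(theta, context, schedule, grid, method=method, step=sim_step)
    out: dict[str, np.ndarray] = {}
    for s in signals:
        idx = np.searchsorted(grid, measurements.times[s])
        out[s] = res.signal(s)[idx]
    return out


def cost_j1(
    theta: ModelParameters,
    measurements: MeasurementSet,
    noise: NoiseModel,
    context: SubjectContext,
    schedule: InputSchedule,
    sim_step: float = 0.25,
    method: str = "fast",
) -> float:
    """Covariance-weighted squared output error over the masked signals.

    Infeasible parameter vectors (no admissible CO solution somewhere on the
    trajectory) return ``INFEASIBLE_PENALTY`` plus a violation measure rather
    than raising, so optimizers can retreat.
    """
    if not measurements.mask:
        raise ValueError("measurement mask is empty; nothing to fit")
    try:
        preds = _predict_signals(
            theta, measurements, context, schedule, sorted(measurements.mask), sim_step, method
        )
    except PhysiologicalInfeasibilityError as err:
        t_fail = float(err.state.get("t", 0.0))
        horizon = float(measurements.all_times[-1])
        # earlier failure = larger violation, keeps the penalty surface sloped
        return INFEASIBLE_PENALTY * (1.0 + (horizon - t_fail) / max(horizon, 1.0))
    j1 = 0.0
    for s in sorted(measurements.mask):
        resid = (preds[s] - measurements.values[s]) / noise.sigma(s)
        j1 += float(resid @ resid)
    return j1


def regularizer_j2(theta: ModelParameters, prior: Prior) -> float:
    """L1 penalty J2 = lam * sum_m |theta_m - theta_bar_m| / b_m."""
    dev = np.abs(theta.to_array() - prior.theta_bar.to_array()) / prior.bounds.ranges
    return float(prior.lam * dev.sum())


# ---------------------------------------------------------------------------
# Results


@dataclass
class FitResult:
    """Outcome of one bounded (regularized) fit."""

    theta: ModelParameters
    j1: float
    j2: float
    d: float
    lam: float
    n_starts: int = 1
    nfev: int = 0
    success: bool = True
    message: str = ""
    start_objectives: tuple[float, ...] = ()
    infeasible: bool = False

    @property
    def objective(self) -> float:
        return self.j1 + self.j2

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.to_dict(),
            "J1": self.j1,
            "J2": self.j2,
            "D": self.d,
            "lambda": self.lam,
            "n_starts": self.n_starts,
            "nfev": self.nfev,
            "success": self.success,
        }


@dataclass
class LambdaSweep:
    """Per-lambda fits along a warm-started sweep, plus the selected knee."""

    lambdas: np.ndarray
    fits: list[FitResult]
    lambda_star: float = np.nan
    knee_index: int = -1
    degenerate: bool = False

    @property
    def j1(self) -> np.ndarray:
        return np.array([f.j1 for f in self.fits])

    @property
    def d(self) -> np.ndarray:
        return np.array([f.d for f in self.fits])

    def fit_at(self, lam: float) -> FitResult:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.fits[idx]

    def selected_fit(self) -> FitResult:
        if self.knee_index < 0:
            raise ValueError("no lambda selected for this sweep")
        return self.fits[self.knee_index]


# ---------------------------------------------------------------------------
# Optimizer core


def _multistart_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: ParameterBounds,
    starts: list[np.ndarray],
    maxfev: int,
    xtol: float = 1e-6,
) -> tuple[np.ndarray, float, int, list[float]]:
    """Bounded Powell from several starts, on unit-box coordinates.

    ``starts`` are parameter-space vectors; returns the best parameter-space
    point, its objective, total nfev, and the best objective per start.
    """
    unit_bounds = [(0.0, 1.0)] * len(bounds.lower)

    def unit_objective(u: np.ndarray) -> float:
        return objective(bounds.denormalize(np.clip(u, 0.0, 1.0)))

    best_x, best_f = None, np.inf
    nfev = 0
    per_start: list[float] = []
    for x0 in starts:
        res = optimize.minimize(
            unit_objective,
            bounds.normalize(x0),
            method="Powell",
            bounds=unit_bounds,
            options={"maxfev": maxfev, "xtol": xtol, "ftol": 1e-8},
        )
        nfev += res.nfev
        per_start.append(float(res.fun))
        if res.fun < best_f:
            best_f = float(res.fun)
            best_x = np.clip(res.x, 0.0, 1.0)
    if best_x is None:
        raise RuntimeError("all optimizer starts failed")
    return bounds.denormalize(best_x), best_f, nfev, per_start


def _residuals_for_record(
    theta: ModelParameters,
    record: SubjectRecord,
    noise: NoiseModel,
    sim_step: float,
) -> np.ndarray:
    """Stacked (pred - data)/sigma over the masked signals of one record.

    Infeasible parameter vectors yield a constant huge residual vector of
    the right length, so least-squares solvers can retreat.
    """
    ms = record.measurements
    n = ms.n_total_masked
    try:
        preds = _predict_signals(
            theta, ms, record.context, record.schedule, sorted(ms.mask), sim_step
        )
    except PhysiologicalInfeasibilityError:
        return np.full(n, np.sqrt(INFEASIBLE_PENALTY / max(n, 1)))
    out = []
    for s in sorted(ms.mask):
        out.append((preds[s] - ms.values[s]) / noise.sigma(s))
    return np.concatenate(out)


def _multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    bounds: ParameterBounds,
    starts: list[np.ndarray],
    max_nfev: int,
) -> tuple[np.ndarray, float, int, list[float]]:
    """Bounded trust-region least squares from several starts (unit box).

    ``max_nfev`` counts residual-vector evaluations per start (the 2-point
    Jacobian costs 11 evaluations per iteration).  Returns the best point in
    parameter space, its sum-of-squares objective, total nfev, and the best
    objective per start.
    """

    def unit_residuals(u: np.ndarray) -> np.ndarray:
        return residual_fn(bounds.denormalize(np.clip(u, 0.0, 1.0)))

    eps = 1e-9  # keep starts strictly inside the box for TRF
    best_x, best_f = None, np.inf
    nfev = 0
    per_start: list[float] = []
    for x0 in starts:
        u0 = np.clip(bounds.normalize(x0), eps, 1.0 - eps)
        try:
            res = optimize.least_squares(
                unit_residuals, u0, bounds=(0.0, 1.0), method="trf",
                x_scale=1.0, xtol=1e-12, ftol=1e-12, gtol=1e-10,
                max_nfev=max_nfev, diff_step=1e-6,
            )
        except Exception:  # singular Jacobian etc.: skip this start
            per_start.append(np.inf)
            continue
        f = float(2.0 * res.cost)  # least_squares cost = 0.5 * sum r^2
        nfev += res.nfev * (len(u0) + 1)
        per_start.append(f)
        if f < best_f:
            best_f = f
            best_x = np.clip(res.x, 0.0, 1.0)
    if best_x is None:
        raise RuntimeError("all least-squares starts failed")
    return bounds.denormalize(best_x), best_f, nfev, per_start


def _make_starts(
    bounds: ParameterBounds,
    n_starts: int,
    seed: int,
    center: np.ndarray | None,
    extra: Sequence[np.ndarray] = (),
) -> list[np.ndarray]:
    """Deterministic multi-start points: warm starts, center, Sobol fill."""
    starts: list[np.ndarray] = []
    starts.extend(np.asarray(x, dtype=float) for x in extra)
    if center is not None:
        starts.append(np.asarray(center, dtype=float))
    n_fill = n_starts - len(starts)
    if n_fill > 0:
        sob = qmc.Sobol(d=len(bounds.lower), scramble=True, seed=seed)
        # shrink toward the box interior to avoid starting on a bound face
        n_pow2 = 1 << max(0, (n_fill - 1).bit_length())
        pts = 0.05 + 0.9 * sob.random_base2(int(np.log2(n_pow2)))[:n_fill]
        starts.extend(bounds.denormalize(p) for p in pts)
    return starts[:n_starts] if n_starts > 0 else starts


# ---------------------------------------------------------------------------
# Estimators (sklearn-style)


class PopulationModel(BaseEstimator):
    """Population-average model: shared theta minimizing pooled J1.

    Parameters
    ----------
    bounds : ParameterBounds, optional
        Parameter box; defaults to the package bounds.
    noise : NoiseModel, optional
        Per-signal measurement SDs weighting the fit cost.
    n_starts : int
        Multi-start count (first start = ``theta_init`` or the box center).
    maxfev : int
        Powell budget per start (forward-model evaluations).
    sim_step : float
        RK4 step (min) of the fast simulation path used during fitting.
    theta_init : ModelParameters, optional
        Preferred first start (e.g. a cached full-population fit).
    random_state : int
        Seed for the Sobol start generator.

    Attributes
    ----------
    theta_bar_ : ModelParameters
        Fitted population-average parameter vector.
    objective_ : float
        Pooled J1 at ``theta_bar_``.
    """

    def __init__(
        self,
        bounds: ParameterBounds | None = None,
        noise: NoiseModel | None = None,
        n_starts: int = 4,
        maxfev: int = 1500,
        sim_step: float = 0.5,
        theta_init: ModelParameters | None = None,
        random_state: int = 0,
    ):
        self.bounds = bounds
        self.noise = noise
        self.n_starts = n_starts
        self.maxfev = maxfev
        self.sim_step = sim_step
        self.theta_init = theta_init
        self.random_state = random_state

    def _resolved(self) -> tuple[ParameterBounds, NoiseModel]:
        return (self.bounds or default_bounds(), self.noise or NoiseModel())

    def fit(self, subjects: Sequence[SubjectRecord], y=None) -> "PopulationModel":
        """Fit the shared parameter vector on a list of subject records."""
        if len(subjects) < 2:
            raise ValueError("population fitting needs at least 2 subjects")
        for rec in subjects:
            if rec.measurements.mask != frozenset({"bv", "co", "map"}):
                raise ValueError(
                    "population fitting requires all three signals "
                    f"(subject {rec.subject_id} has mask {set(rec.measurements.mask)})"
                )
        bounds, noise = self._resolved()

        def residual_fn(x: np.ndarray) -> np.ndarray:
            theta = ModelParameters.from_array(x)
            return np.concatenate(
                [_residuals_for_record(theta, r, noise, self.sim_step) for r in subjects]
            )

        center = (
            self.theta_init.to_array()
            if self.theta_init is not None
            else 0.5 * (bounds.lower + bounds.upper)
        )
        starts = _make_starts(bounds, self.n_starts, self.random_state, center)
        # the pooled likelihood is a smooth least-squares problem: use the
        # bounded trust-region solver (budget in residual evaluations)
        x, fbest, nfev, per_start = _multistart_least_squares(
            residual_fn, bounds, starts, max_nfev=max(20, self.maxfev // 12)
        )
        self.theta_bar_ = ModelParameters.from_array(x)
        self.objective_ = fbest
        self.nfev_ = nfev
        self.start_objectives_ = tuple(per_start)
        self.n_subjects_ = len(subjects)
        return self

    def predict(self, record: SubjectRecord, time_grid: np.ndarray | None = None):
        """Simulate the population-average model for one subject."""
        grid = record.measurements.all_times if time_grid is None else np.asarray(time_grid)
        return simulate_subject(
            self.theta_bar_, record.context, record.schedule, grid, method="fast",
            step=self.sim_step,
        )

    def prior(self, lam: float = 0.0) -> Prior:
        """Laplace prior centered on the fitted population mode."""
        bounds, _ = self._resolved()
        return Prior(self.theta_bar_, bounds, lam)


class IndividualizedModel(BaseEstimator):
    """Regularized individualization of the model to one subject.

    ``lam`` may be a number (fixed weight; 0 = maximum likelihood) or
    ``"auto"`` to select the knee of the (J1, D) curve over ``lambda_grid``
    via a warm-started sweep.

    Attributes (after ``fit``)
    --------------------------
    theta_ : ModelParameters — the individualized estimate theta_hat
    j1_, j2_, d_ : float — fit cost, penalty, and deviation distance
    lambda_ : float — the regularization weight actually used
    sweep_ : LambdaSweep | None — the sweep, when ``lam="auto"``
    """

    def __init__(
        self,
        prior: Prior | None = None,
        lam: float | str = 0.0,
        lambda_grid: np.ndarray | None = None,
        noise: NoiseModel | None = None,
        n_starts: int = 4,
        maxfev: int = 1200,
        sweep_maxfev: int = 500,
        sim_step: float = 0.5,
        random_state: int = 0,
    ):
        self.prior = prior
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.noise = noise
        self.n_starts = n_starts
        self.maxfev = maxfev
        self.sweep_maxfev = sweep_maxfev
        self.sim_step = sim_step
        self.random_state = random_state

    def _fit_single(
        self,
        record: SubjectRecord,
        prior: Prior,
        noise: NoiseModel,
        n_starts: int,
        maxfev: int,
        warm: Sequence[np.ndarray] = (),
    ) -> FitResult:
        bounds = prior.bounds
        starts = _make_starts(
            bounds, n_starts, self.random_state, prior.theta_bar.to_array(), extra=warm
        )
        if prior.lam == 0.0:
            # maximum likelihood: smooth least squares, trust-region solver
            def residual_fn(x: np.ndarray) -> np.ndarray:
                return _residuals_for_record(
                    ModelParameters.from_array(x), record, noise, self.sim_step
                )

            x, fbest, nfev, per_start = _multistart_least_squares(
                residual_fn, bounds, starts, max_nfev=max(20, maxfev // 12)
            )
        else:
            # the exact L1 objective is non-smooth at the prior mode: Powell
            def objective(x: np.ndarray) -> float:
                theta = ModelParameters.from_array(x)
                return (
                    cost_j1(theta, record.measurements, noise, record.context,
                            record.schedule, self.sim_step)
                    + regularizer_j2(theta, prior)
                )

            x, fbest, nfev, per_start = _multistart_minimize(objective, bounds, starts, maxfev)
        theta = ModelParameters.from_array(x)
        j1 = cost_j1(theta, record.measurements, noise, record.context, record.schedule,
                     self.sim_step)
        j2 = regularizer_j2(theta, prior)
        dev = np.abs(theta.to_array() - prior.theta_bar.to_array()) / bounds.ranges
        return FitResult(
            theta=theta,
            j1=j1,
            j2=j2,
            d=float(dev.sum()),
            lam=prior.lam,
            n_starts=len(starts),
            nfev=nfev,
            success=j1 < INFEASIBLE_PENALTY,
            start_objectives=tuple(per_start),
            infeasible=j1 >= INFEASIBLE_PENALTY,
        )

    def fit(self, record: SubjectRecord, y=None) -> "IndividualizedModel":
        if self.prior is None:
            raise ValueError("IndividualizedModel requires a prior (population mode + bounds)")
        noise = self.noise or NoiseModel()
        if isinstance(self.lam, str):
            if self.lam != "auto":
                raise ValueError(f"lam must be a number or 'auto', got {self.lam!r}")
            grid = self.lambda_grid if self.lambda_grid is not None else default_lambda_grid()
            sweep = sweep_lambda(
                record,
                self.prior,
                noise,
                grid,
                n_starts=self.n_starts,
                maxfev=self.maxfev,
                sweep_maxfev=self.sweep_maxfev,
                sim_step=self.sim_step,
                random_state=self.random_state,
            )
            best = sweep.selected_fit()
            self.sweep_ = sweep
            self.lambda_ = sweep.lambda_star
            result = best
        else:
            lam = float(self.lam)
            result = self._fit_single(
                record, self.prior.with_lambda(lam), noise, self.n_starts, self.maxfev
            )
            self.sweep_ = None
            self.lambda_ = lam
        self.result_ = result
        self.theta_ = result.theta
        self.j1_ = result.j1
        self.j2_ = result.j2
        self.d_ = result.d
        return self

    def predict(self, record: SubjectRecord, time_grid: np.ndarray | None = None):
        """Simulate the individualized model (all signals) for a subject."""
        grid = record.measurements.all_times if time_grid is None else np.asarray(time_grid)
        return simulate_subject(
            self.theta_, record.context, record.schedule, grid, method="fast",
            step=self.sim_step,
        )


# ---------------------------------------------------------------------------
# Lambda sweep + knee selection


def sweep_lambda(
    record: SubjectRecord,
    prior: Prior,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    n_starts: int = 4,
    maxfev: int = 1200,
    sweep_maxfev: int = 500,
    sim_step: float = 0.5,
    random_state: int = 0,
    select: bool = True,
) -> LambdaSweep:
    """Trace (J1, D) along a lambda grid, warm-starting each fit.

    The lambda=0 entry is a full multi-start maximum-likelihood fit.  The
    regularized entries are traced in the homotopy direction, descending
    from lambda_max (where the estimate collapses onto the prior mode) with
    each fit warm-started from its predecessor, so deviations activate in
    sensitivity order as the penalty relaxes.  A final path-consistency
    pass re-selects, for every lambda, the best candidate among all vectors
    fitted anywhere on the path (and the prior mode itself): picking each
    lambda's minimizer from one shared candidate set makes D(lambda)
    non-increasing and J1(lambda) non-decreasing exactly (an exchange
    argument), and can only improve each fit.
    """
    noise = noise or NoiseModel()
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be 1-D, sorted, with distinct values")
    if grid[0] != 0.0:
        raise ValueError("lambda grid must include 0")
    est = IndividualizedModel(
        prior=prior, noise=noise, n_starts=n_starts, maxfev=maxfev,
        sweep_maxfev=sweep_maxfev, sim_step=sim_step, random_state=random_state,
    )

    def safe_fit(lam: float, nst: int, budget: int, warm: list[np.ndarray]) -> FitResult:
        try:
            return est._fit_single(record, prior.with_lambda(lam), noise, nst, budget,
                                   warm=warm)
        except RuntimeError as err:  # keep sweeping past a failed grid point
            return FitResult(
                theta=prior.theta_bar, j1=np.inf, j2=0.0, d=0.0, lam=float(lam),
                success=False, message=str(err),
            )

    fit0 = safe_fit(0.0, n_starts, maxfev, [])
    descending: list[FitResult] = []
    warm = [prior.theta_bar.to_array()]
    for lam in grid[:0:-1]:
        fit = safe_fit(float(lam), 1, sweep_maxfev, warm)
        descending.append(fit)
        if fit.success:
            warm = [fit.theta.to_array()]
    fits = [fit0] + descending[::-1]

    # path-consistency pass over the shared candidate set
    candidates: list[tuple[ModelParameters, float, float]] = []  # (theta, J1, D)
    seen: set[bytes] = set()
    ranges = prior.bounds.ranges
    bar = prior.theta_bar.to_array()
    pool = [f.theta for f in fits if f.success] + [prior.theta_bar]
    # soft-thresholded interpolates of the fitted vectors toward the mode:
    # the exact L1 solution path of the orthogonal-design analogue, which
    # fills in the compression levels the budgeted per-lambda fits may miss
    for theta in [f.theta for f in fits if f.success]:
        delta = (theta.to_array() - bar) / ranges
        top = np.max(np.abs(delta))
        if top <= 0:
            continue
        for tau in np.geomspace(max(top * 1e-3, 1e-6), top, 8)[:-1]:
            shrunk = np.sign(delta) * np.maximum(np.abs(delta) - tau, 0.0)
            pool.append(ModelParameters.from_array(bar + shrunk * ranges))
    for theta in pool:
        key = theta.to_array().tobytes()
        if key in seen:
            continue
        seen.add(key)
        j1 = cost_j1(theta, record.measurements, noise, record.context, record.schedule, sim_step)
        d = float((np.abs(theta.to_array() - bar) / ranges).sum())
        candidates.append((theta, j1, d))
    if candidates:
        for i, lam in enumerate(grid):
            if not fits[i].success:
                continue
            # stable argmin: ties keep the earlier (smaller-J1-index) candidate
            best = min(enumerate(candidates), key=lambda kv: (kv[1][1] + lam * kv[1][2], kv[0]))
            theta, j1, d = best[1]
            fits[i] = FitResult(
                theta=theta, j1=j1, j2=float(lam) * d, d=d, lam=float(lam),
                n_starts=fits[i].n_starts, nfev=fits[i].nfev,
                success=j1 < INFEASIBLE_PENALTY,
                start_objectives=fits[i].start_objectives,
                infeasible=j1 >= INFEASIBLE_PENALTY,
            )

    sweep = LambdaSweep(lambdas=grid, fits=fits)
    if select:
        lam_star, idx, degenerate = select_lambda(sweep)
        sweep.lambda_star = lam_star
        sweep.knee_index = idx
        sweep.degenerate = degenerate
    return sweep


def select_lambda(sweep: LambdaSweep) -> tuple[float, int, bool]:
    """Knee of the (J1, D) curve: maximum perpendicular distance to the chord.

    Both axes are min-max normalized to [0, 1]; the knee is the point
    farthest from the straight line joining the curve's endpoints, ties
    broken toward smaller lambda.  A degenerate curve (J1 or D numerically
    constant) returns the smallest nonzero lambda with a degeneracy flag.

    Returns ``(lambda_star, index, degenerate)``.
    """
    ok = np.array([f.success for f in sweep.fits])
    if ok.sum() < 4:
        raise ValueError("lambda selection needs at least 4 successful fits")
    lam = sweep.lambdas[ok]
    j1 = sweep.j1[ok]
    d = sweep.d[ok]
    j1_span = j1.max() - j1.min()
    d_span = d.max() - d.min()
    scale = max(abs(j1).max(), abs(d).max(), 1e-300)
    if j1_span <= 1e-9 * scale or d_span <= 1e-9 * scale:
        nz = np.nonzero(sweep.lambdas > 0)[0]
        idx = int(nz[0])
        return float(sweep.lambdas[idx]), idx, True
    x = (j1 - j1.min()) / j1_span
    y = (d - d.min()) / d_span
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    # perpendicular distance of each curve point to the endpoint chord
    dist = np.abs(chord[0] * (y - p0[1]) - chord[1] * (x - p0[0])) / norm
    best = int(np.argmax(dist))  # argmax takes the first maximum: smallest-lambda tie-break
    full_idx = int(np.nonzero(ok)[0][best])
    return float(lam[best]), full_idx, False


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_population(
    subjects: Sequence[SubjectRecord],
    noise: NoiseModel | None = None,
    bounds: ParameterBounds | None = None,
    **kwargs,
) -> ModelParameters:
    """Population-average parameter vector (thin wrapper over PopulationModel)."""
    est = PopulationModel(bounds=bounds, noise=noise, **kwargs).fit(subjects)
    return est.theta_bar_


def individualize(
    record: SubjectRecord,
    prior: Prior,
    noise: NoiseModel | None = None,
    lam: float | str | None = None,
    **kwargs,
) -> FitResult:
    """Individualize to one subject (thin wrapper over IndividualizedModel).

    When ``lam`` is None the prior's own weight is used.
    """
    lam = prior.lam if lam is None else lam
    est = IndividualizedModel(prior=prior, lam=lam, noise=noise, **kwargs).fit(record)
    return est.result_
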