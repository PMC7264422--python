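"""Leave-one-out individualization study under the three scarcity cases.

For each subject i the population-average model theta_bar_i is fitted on
the remaining N-1 subjects (maximum likelihood, all three signals), then the
model is individualized to subject i under each requested scarcity case both
without regularization (lambda = 0) and with a knee-selected weight.  Per
subject the study records the output error e1, the internal-state error e2,
the deviation distance D and the signed per-parameter deviations, and
aggregates them across subjects; the regularized-vs-unregularized e2
contrasts in the withheld-signal cases are compared with the exact Wilcoxon
signed-rank test under a Bonferroni correction over the contrasts performed.

Because the pooled maximum-likelihood objective changes little when a single
subject is excluded, each leave-one-out fit is warm-started from a cached
full-population fit and refined with a reduced budget (a documented
computational shortcut, configurable via ``loo_maxfev``/``loo_starts``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import (
    FitResult,
    IndividualizedModel,
    PopulationModel,
    default_lambda_grid,
    sweep_lambda,
)
from .evaluation import (
    deviation_distance,
    normalized_deviations,
    paired_signed_rank_bonferroni,
)
from .measurements import CASE_MASKS, MeasurementSet, NoiseModel, SubjectRecord
from .model import simulate_subject
from .parameters import PARAM_NAMES, ModelParameters, ParameterBounds, Prior, default_bounds

__all__ = ["StudyConfig", "SubjectCaseResult", "StudyResult", "run_leave_one_out_study", "export_reports"]

MODEL_COLUMNS = ("population_average", "individualized_lambda0", "individualized_regularized")


@dataclass(frozen=True)
class StudyConfig:
    """Study settings: cases, lambda policy, optimization budgets."""

    cases: tuple[int, ...] = (1, 2, 3)
    lambda_policy: str = "auto"  # "auto" (knee) | "fixed"
    fixed_lambda: float = 0.1
    lambda_grid: np.ndarray = field(default_factory=lambda: default_lambda_grid(10.0, 12))
    n_starts: int = 2
    maxfev: int = 1000  # budget of each lambda=0 individual fit (per start)
    sweep_maxfev: int = 250  # budget of each warm-started sweep fit
    pop_starts: int = 2
    pop_maxfev: int = 1200  # full-population fit budget (per start)
    loo_starts: int = 1
    loo_maxfev: int = 250  # per leave-one-out refinement
    sim_step: float = 0.5  # min, RK4 step during fitting
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.cases) - set(CASE_MASKS)
        if bad:
            raise ValueError(f"unknown cases: {sorted(bad)}")
        if self.lambda_policy not in ("auto", "fixed"):
            raise ValueError("lambda_policy must be 'auto' or 'fixed'")


@dataclass
class SubjectCaseResult:
    """All per-subject metrics for one scarcity case."""

    subject_id: str
    case: int
    lambda_star: float
    fits: dict[str, FitResult | None]  # keyed by MODEL_COLUMNS; pop avg has None
    e1: dict[str, float]
    e2: dict[str, float | None]
    rmse: dict[str, dict[str, float]]  # column -> signal -> RMSE
    d: dict[str, float]
    deviations: dict[str, np.ndarray]  # column -> signed normalized deviations
    sweep_table: pd.DataFrame | None = None
    sweep: object | None = None  # the LambdaSweep when lambda_policy == "auto"


@dataclass
class StudyResult:
    subjects: list[str]
    cases: tuple[int, ...]
    theta_bars: dict[str, ModelParameters]
    per_case: dict[int, list[SubjectCaseResult]]
    p_values: dict[str, float]
    failures: list[str]

    def summary_frame(self, case: int) -> pd.DataFrame:
        """Table-style summary: rows = metrics, columns = model variants."""
        rows = {}
        results = self.per_case[case]
        for metric in ("bv", "co", "map"):
            rows[f"{metric.upper()}"] = {
                col: np.mean([r.rmse[col][metric] for r in results]) for col in MODEL_COLUMNS
            }
        rows["e1"] = {col: np.mean([r.e1[col] for r in results]) for col in MODEL_COLUMNS}
        if all(r.e2[MODEL_COLUMNS[0]] is not None for r in results):
            rows["e2"] = {col: np.mean([r.e2[col] for r in results]) for col in MODEL_COLUMNS}
        rows["D"] = {col: np.mean([r.d[col] for r in results]) for col in MODEL_COLUMNS}
        rows["lambda"] = {
            "population_average": 0.0,
            "individualized_lambda0": 0.0,
            "individualized_regularized": np.mean([r.lambda_star for r in results]),
        }
        return pd.DataFrame(rows).T[list(MODEL_COLUMNS)]


def _metrics_for_theta(
    theta: ModelParameters,
    record: SubjectRecord,
    noise: NoiseModel,
    prior_parts: tuple[ModelParameters, ParameterBounds],
    sim_step: float,
) -> tuple[float, float | None, dict[str, float], float, np.ndarray]:
    """(e1_i, e2_i, per-signal RMSE, D, signed deviations) for one subject."""
    ms = record.measurements
    res = simulate_subject(theta, record.context, record.schedule, ms.all_times,
                           method="fast", step=sim_step)
    preds = {}
    for s in ms.times:
        idx = np.searchsorted(ms.all_times, ms.times[s])
        preds[s] = res.signal(s)[idx]

    def grouped(signals) -> float:
        sq, n = 0.0, 0
        for s in signals:
            r = (preds[s] - ms.values[s]) / noise.sigma(s)
            sq += float(r @ r)
            n += len(r)
        return np.sqrt(sq) / np.sqrt(n)

    e1 = grouped(sorted(ms.mask))
    withheld = ms.withheld()
    e2 = grouped(sorted(withheld)) if withheld else None
    rmse = {s: float(np.sqrt(np.mean((preds[s] - ms.values[s]) ** 2))) for s in ms.times}
    d = deviation_distance(theta, prior_parts)
    dev = normalized_deviations(theta, prior_parts)
    return e1, e2, rmse, d, dev


def run_leave_one_out_study(
    subjects: Sequence[SubjectRecord],
    config: StudyConfig | None = None,
    noise: NoiseModel | None = None,
    bounds: ParameterBounds | None = None,
    theta_init: ModelParameters | None = None,
    verbose: bool = False,
) -> StudyResult:
    """Run the full leave-one-out individualization study.

    ``theta_init`` seeds the cached full-population fit (defaults to the
    bounds box center).  Per-subject failures are recorded in
    ``result.failures`` and excluded from aggregates, never silently.
    """
    config = config or StudyConfig()
    noise = noise or NoiseModel()
    bounds = bounds or default_bounds()
    if len(subjects) < 3:
        raise ValueError("leave-one-out study needs at least 3 subjects")

    # Cached full-population fit; each leave-one-out fit refines from it.
    full = PopulationModel(
        bounds=bounds, noise=noise, n_starts=config.pop_starts, maxfev=config.pop_maxfev,
        sim_step=config.sim_step, theta_init=theta_init, random_state=config.seed,
    ).fit(list(subjects))
    if verbose:
        print(f"[study] full-population fit: J = {full.objective_:.3f}")

    theta_bars: dict[str, ModelParameters] = {}
    for i, rec in enumerate(subjects):
        others = [r for j, r in enumerate(subjects) if j != i]
        loo = PopulationModel(
            bounds=bounds, noise=noise, n_starts=config.loo_starts, maxfev=config.loo_maxfev,
            sim_step=config.sim_step, theta_init=full.theta_bar_, random_state=config.seed,
        ).fit(others)
        theta_bars[rec.subject_id] = loo.theta_bar_
        if verbose:
            print(f"[study] LOO prior for {rec.subject_id}: J = {loo.objective_:.3f}")

    per_case: dict[int, list[SubjectCaseResult]] = {c: [] for c in config.cases}
    failures: list[str] = []
    for i, rec in enumerate(subjects):
        theta_bar = theta_bars[rec.subject_id]
        prior0 = Prior(theta_bar, bounds, 0.0)
        prior_parts = (theta_bar, bounds)
        for case in config.cases:
            crec = rec.with_case(case)
            try:
                if config.lambda_policy == "auto":
                    # one sweep provides both the lambda=0 fit (first entry)
                    # and the knee-selected regularized fit
                    sweep = sweep_lambda(
                        crec, prior0, noise, config.lambda_grid,
                        n_starts=config.n_starts, maxfev=config.maxfev,
                        sweep_maxfev=config.sweep_maxfev, sim_step=config.sim_step,
                        random_state=config.seed,
                    )
                    fit0 = sweep.fits[0]
                    fit_reg = sweep.selected_fit()
                    lam_star = sweep.lambda_star
                else:
                    sweep = None
                    fit0 = IndividualizedModel(
                        prior=prior0, lam=0.0, noise=noise, n_starts=config.n_starts,
                        maxfev=config.maxfev, sim_step=config.sim_step,
                        random_state=config.seed,
                    ).fit(crec).result_
                    fit_reg = IndividualizedModel(
                        prior=prior0.with_lambda(config.fixed_lambda), lam=config.fixed_lambda,
                        noise=noise, n_starts=config.n_starts, maxfev=config.maxfev,
                        sim_step=config.sim_step, random_state=config.seed,
                    ).fit(crec).result_
                    lam_star = config.fixed_lambda
                if not (fit0.success and fit_reg.success):
                    raise RuntimeError("individualization did not reach a feasible fit")
            except RuntimeError as err:
                failures.append(f"{rec.subject_id}/case{case}: {err}")
                continue

            e1s, e2s, rmses, ds, devs = {}, {}, {}, {}, {}
            for col, theta in (
                ("population_average", theta_bar),
                ("individualized_lambda0", fit0.theta),
                ("individualized_regularized", fit_reg.theta),
            ):
                e1, e2, rmse, d, dev = _metrics_for_theta(theta, crec, noise, prior_parts,
                                                          config.sim_step)
                e1s[col], e2s[col], rmses[col], ds[col], devs[col] = e1, e2, rmse, d, dev

            sweep_table = None
            if sweep is not None:
                withheld = crec.measurements.withheld()
                e2_col = []
                for f in sweep.fits:
                    if not withheld or not f.success:
                        e2_col.append(np.nan)
                        continue
                    e2_val = _metrics_for_theta(f.theta, crec, noise, prior_parts,
                                                config.sim_step)[1]
                    e2_col.append(np.nan if e2_val is None else e2_val)
                sweep_table = pd.DataFrame(
                    {"lambda": sweep.lambdas, "J1": sweep.j1, "D": sweep.d, "e2": e2_col}
                )
            per_case[case].append(
                SubjectCaseResult(
                    subject_id=rec.subject_id, case=case, lambda_star=lam_star,
                    fits={"population_average": None, "individualized_lambda0": fit0,
                          "individualized_regularized": fit_reg},
                    e1=e1s, e2=e2s, rmse=rmses, d=ds, deviations=devs,
                    sweep_table=sweep_table, sweep=sweep,
                )
            )
            if verbose:
                msg = f"[study] {rec.subject_id} case {case}: D0={ds['individualized_lambda0']:.2f} " \
                      f"Dreg={ds['individualized_regularized']:.2f} lam*={lam_star:.3g}"
                print(msg)

    # Paired contrasts: regularized vs lambda=0 e2, in the withheld-signal cases.
    contrast_cases = [c for c in config.cases if c in (2, 3) and per_case[c]]
    p_values: dict[str, float] = {}
    for c in contrast_cases:
        a = [r.e2["individualized_regularized"] for r in per_case[c]]
        b = [r.e2["individualized_lambda0"] for r in per_case[c]]
        if len(a) >= 5:
            p, _ = paired_signed_rank_bonferroni(a, b, n_comparisons=len(contrast_cases))
            p_values[f"case{c}_e2_reg_vs_lambda0"] = p

    return StudyResult(
        subjects=[r.subject_id for r in subjects],
        cases=config.cases,
        theta_bars=theta_bars,
        per_case=per_case,
        p_values=p_values,
        failures=failures,
    )


def export_reports(result: StudyResult, out_dir: str | Path) -> list[Path]:
    """Write summary CSVs, per-subject sweeps, deviations, and p-values.

    Returns the list of files written; an empty case list writes nothing.
    """
    out = Path(out_dir)
    written: list[Path] = []
    if not result.cases:
        return written
    out.mkdir(parents=True, exist_ok=True)
    for case in result.cases:
        frame = result.summary_frame(case)
        path = out / f"summary_case{case}.csv"
        frame.to_csv(path, index_label="metric")
        written.append(path)
        # per-subject lambda sweeps
        for r in result.per_case[case]:
            if r.sweep_table is not None:
                p = out / f"sweep_case{case}_{r.subject_id}.csv"
                r.sweep_table.to_csv(p, index=False)
                written.append(p)
        # long-format per-parameter deviations
        rows = []
        for r in result.per_case[case]:
            for col in MODEL_COLUMNS[1:]:
                for name, value in zip(PARAM_NAMES, r.deviations[col]):
                    rows.append(
                        {"subject_id": r.subject_id, "case": case, "model": col,
                         "parameter": name, "normalized_deviation": value}
                    )
        p = out / f"deviations_case{case}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    p = out / "signed_rank_p_values.json"
    p.write_text(json.dumps(result.p_values, indent=1))
    written.append(p)
    return written
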