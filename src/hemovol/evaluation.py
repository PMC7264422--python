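"""Error metrics, deviation distance, and paired significance testing.

Two normalized RMSE metrics score an individualized model:

* ``e1`` (output error) — over the signals that *were* used in fitting;
* ``e2`` (state error) — over the withheld signals, i.e. the internal-state
  prediction test (BV in case 2; BV and CO in case 3).

Both use the same per-subject grouping: for subject i with signal set S,

    r_i = sqrt( sum_{s in S} ||(pred_s - data_s)/sigma_s||^2 ) / sqrt(n_i)

with n_i the total sample count over S, and the metric is the mean of r_i
over subjects.  For a single subject and signal this is RMSE/sigma.  The
grouping (1/N outside the root, 1/sqrt(n) inside) is this package's reading
of the metric's "mean normalized RMSE" definition and is deliberately
invariant to jointly rescaling a signal's units and its sigma.

The deviation distance D = sum_m |theta_m - theta_bar_m| / b_m measures how
far an individualized vector moved from the population mode in units of the
physiological ranges; for lam > 0, D = J2 / lam exactly.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .measurements import MeasurementSet, NoiseModel
from .parameters import ModelParameters, ParameterBounds, Prior

__all__ = [
    "normalized_output_error",
    "output_error_e1",
    "state_error_e2",
    "deviation_distance",
    "normalized_deviations",
    "paired_signed_rank_bonferroni",
    "per_signal_rmse",
]


def _subject_error(
    pred: Mapping[str, np.ndarray],
    ms: MeasurementSet,
    noise: NoiseModel,
    signals: Iterable[str],
) -> float:
    sq = 0.0
    n = 0
    for s in signals:
        if ms.count(s) == 0:
            raise ValueError(f"no samples for signal {s!r}")
        resid = (np.asarray(pred[s], dtype=float) - ms.values[s]) / noise.sigma(s)
        if len(resid) != ms.count(s):
            raise ValueError(f"prediction length mismatch for signal {s!r}")
        sq += float(resid @ resid)
        n += ms.count(s)
    if n == 0:
        raise ValueError("empty signal set")
    return np.sqrt(sq) / np.sqrt(n)


def normalized_output_error(
    predictions: Sequence[Mapping[str, np.ndarray]],
    measurements: Sequence[MeasurementSet],
    noise: NoiseModel,
    signals: Iterable[str],
) -> float:
    """Mean over subjects of the per-subject normalized RMSE over ``signals``.

    ``predictions[i][s]`` must be the model output for subject i, signal s,
    sampled exactly at ``measurements[i].times[s]``.
    """
    signals = sorted(set(signals))
    if not signals:
        raise ValueError("signal set is empty")
    if len(predictions) != len(measurements) or len(measurements) == 0:
        raise ValueError("predictions and measurements must be equal-length, non-empty")
    errs = [
        _subject_error(p, m, noise, signals) for p, m in zip(predictions, measurements)
    ]
    return float(np.mean(errs))


def output_error_e1(
    predictions: Sequence[Mapping[str, np.ndarray]],
    measurements: Sequence[MeasurementSet],
    noise: NoiseModel,
    mask: Iterable[str] | None = None,
) -> float:
    """Output prediction error e1 over the fitted signals.

    ``mask=None`` uses each measurement set's own mask (they must agree).
    """
    if mask is None:
        masks = {m.mask for m in measurements}
        if len(masks) != 1:
            raise ValueError("measurement sets carry differing masks; pass mask explicitly")
        mask = next(iter(masks))
    mask = frozenset(mask)
    if not mask:
        raise ValueError("e1 is undefined for an empty fitted-signal mask")
    return normalized_output_error(predictions, measurements, noise, mask)


def state_error_e2(
    predictions: Sequence[Mapping[str, np.ndarray]],
    measurements: Sequence[MeasurementSet],
    noise: NoiseModel,
    withheld: Iterable[str] | None = None,
) -> float | None:
    """Internal-state prediction error e2 over the withheld signals.

    Pools each subject's withheld signals inside one root before averaging
    over subjects.  Returns None when there is no withheld signal (case 1):
    a defined-empty result, not zero.
    """
    if withheld is None:
        sets = {m.withheld() for m in measurements}
        if len(sets) != 1:
            raise ValueError("measurement sets withhold differing signals; pass withheld explicitly")
        withheld = next(iter(sets))
    withheld = frozenset(withheld)
    if not withheld:
        return None
    return normalized_output_error(predictions, measurements, noise, withheld)


def per_signal_rmse(
    predictions: Sequence[Mapping[str, np.ndarray]],
    measurements: Sequence[MeasurementSet],
    signal: str,
) -> float:
    """Mean over subjects of the plain per-subject RMSE of one signal."""
    errs = []
    for p, m in zip(predictions, measurements):
        resid = np.asarray(p[signal], dtype=float) - m.values[signal]
        errs.append(np.sqrt(np.mean(resid**2)))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# Parameter-space metrics


def _prior_parts(prior: Prior | tuple[ModelParameters, ParameterBounds]):
    if isinstance(prior, Prior):
        return prior.theta_bar, prior.bounds
    theta_bar, bounds = prior
    return theta_bar, bounds


def normalized_deviations(
    theta_hat: ModelParameters,
    prior: Prior | tuple[ModelParameters, ParameterBounds],
) -> np.ndarray:
    """Signed per-parameter deviations (theta_hat_m - theta_bar_m)/b_m."""
    theta_bar, bounds = _prior_parts(prior)
    return (theta_hat.to_array() - theta_bar.to_array()) / bounds.ranges


def deviation_distance(
    theta_hat: ModelParameters,
    prior: Prior | tuple[ModelParameters, ParameterBounds],
) -> float:
    """Range-normalized L1 distance D from the population mode (= J2/lam)."""
    return float(np.abs(normalized_deviations(theta_hat, prior)).sum())


# ---------------------------------------------------------------------------
# Paired statistics


def paired_signed_rank_bonferroni(
    a: Sequence[float],
    b: Sequence[float],
    n_comparisons: int = 1,
) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired samples, Bonferroni-adjusted.

    Zero differences are dropped before ranking.  Exact null enumeration is
    used up to 25 informative pairs; the normal approximation with
    continuity correction above that.  Returns ``(p_adjusted, degenerate)``
    where ``degenerate`` flags the all-differences-zero case (p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    diffs = a - b
    nonzero = diffs[diffs != 0.0]
    if len(nonzero) == 0:
        return 1.0, True
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero,
        alternative="two-sided",
        method=method,
        correction=(method == "approx"),
        zero_method="wilcox",
    )
    return float(min(1.0, res.pvalue * n_comparisons)), False
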