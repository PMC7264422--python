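# Methods

## Model and assumptions

The forward model couples macroscopic blood-volume kinetics, an implicit
cardiac-output (CO) equilibrium, and first-order short-term arterial
pressure regulation. It deliberately excludes pulsatile (beat-by-beat)
hemodynamics, long-term neurohumoral volume/pressure control
(renin–angiotensin, ADH), and any multi-compartment interstitial
description: the intended horizon is a 180-minute hemorrhage/resuscitation
protocol during which short-term regulation dominates. Heart rate is an
input, not a state; the default is a constant per-subject value (a
configurable signal is accepted by the reference integrator) because the
measured data the analysis assumes (BV, CO, MAP) carry no HR trajectory.

States are deviations from the pre-protocol baseline: ΔV_B (L) and ΔTPR
(mmHg·min/L), plus the exactly-integrable input integrals. CO is algebraic:
at every evaluation the unique positive root of

    CO = HR/(A + (A/E_s)·HR·TPR) · log(1 − (γk/B)·TPR·CO + (γ/(BC_s))(V_B − ηV_B0))

is found by a bracketed solve; the right side is strictly decreasing in CO
whenever TPR > 0, so a sign change brackets exactly one root. States for
which the log argument cannot stay positive (circulatory collapse) raise a
typed infeasibility error carrying the offending state; inside estimation
objectives this is converted to a large finite penalty (1e12 plus an
earlier-failure-is-worse slope) so bounded searches can retreat.

A useful closed form anchors the resting state: at equilibrium ΔTPR = 0
forces MAP = MAP_target, hence TPR·CO = MAP_target, making the log argument
constant and

    CO_0 = HR·(log(1 + (γ/BC_s)(1−η)V_B0 − (γk/B)·MAP_target) − (A/E_s)·MAP_target)/A.

The generator uses this to place every virtual subject exactly on its model
equilibrium, and it is also the package's "anchor" device: A is rescaled per
subject so the equilibrium CO matches a target baseline CO.

## Parameters, units, defaults

All quantities are in L, L/min, mmHg, min. The 11 lumped parameters, their
package-default bounds (the ranges b_m that normalize the prior), and the
default population mode:

| parameter   | meaning                          | bounds          | mode  |
|-------------|----------------------------------|-----------------|-------|
| alpha_u     | fluid-gain partition exponent    | [1, 6]          | 3.0   |
| alpha_v     | fluid-loss partition exponent    | [0.25, 3.5]     | 1.8   |
| K_p (1/min) | volume-exchange gain             | [0.05, 0.8]     | 0.25  |
| A           | PV-loop shape (lumped)           | [10, 40]        | 22.18 |
| A_over_Es   | A/E_s (lumped)                   | [0.0005, 0.006] | 0.002 |
| gk_over_B (1/mmHg) | γk/B                      | [0.001, 0.01]   | 0.004 |
| g_over_BCs (1/L)   | γ/(B·C_s)                 | [1, 6]          | 3.0   |
| eta         | unstressed-volume fraction       | [0.35, 0.8]     | 0.59  |
| k_TPR       | MAP-regulation gain              | [0.005, 0.1]    | 0.015 |
| p_TPR (1/min) | MAP-regulation rate            | [0.02, 0.3]     | 0.1   |
| MAP_target (mmHg) | intrinsic set point        | [70, 110]       | 91.22 |

Units of the purely lumped constants (A, A/E_s, k_TPR) follow from
dimensional consistency of the CO equation and are documented, not
enforced. Bounds and mode are the package's own calibration (no published
parameter table exists for this lumping): the mode was chosen once, by the
closed-form baseline algebra plus a simulation scan, so that a typical
subject (V_B0 2.37 L, HR 90) rests at CO 4.4 L/min / MAP 91.2 mmHg and a
25 ml/kg 15-minute hemorrhage lands near the published post-hemorrhage
population means; the bounds are generous physiological boxes around it.
Both are constructor arguments everywhere.

Measurement noise defaults (diagonal Σ): σ_BV = 0.1 L, σ_CO = 0.3 L/min,
σ_MAP = 5 mmHg — nominal instrument-noise figures for dilution BV, a
pulmonary-artery flow probe, and an arterial catheter; configurable and not
derived from any published covariance.

## Numerical integration

Two integrators share one model definition:

* **Reference path** — LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8 /
  atol 1e-10, restarted at every schedule breakpoint so the
  piecewise-constant inputs never straddle an adaptive step; input
  integrals are computed exactly from the schedule (piecewise linear).
* **Fast path** — a numba-compiled fixed-step RK4 whose step sequence is
  aligned to the union of schedule breakpoints and output times (default
  step 0.5 min inside estimation, 0.1 min in the generator). The in-RHS CO
  root is a safeguarded Newton iteration (bracketed, warm-started from the
  previous stage). At step 0.5 the two paths agree to ~1e-7 relative on all
  signals over the full protocol; the test suite also checks the reference
  path against an independent 0.01-min RK4 re-implementation to 1e-4.

The estimators use the fast path because one study performs on the order of
10^5 forward simulations; aligning steps to breakpoints also makes
re-simulation of a stored schedule bit-for-bit reproducible, which the
generator's truth sidecars rely on.

## Estimation

* **Population-average model** (prior mode θ̄): pooled maximum likelihood
  over L subjects with all three signals. The pooled objective is a smooth
  least-squares problem, so it is solved with scipy's bounded
  trust-region-reflective `least_squares` on range-normalized coordinates,
  multi-started (prior guess plus scrambled-Sobol points). λ = 0
  individual fits use the same solver.
* **Regularized individualization**: the exact L1 objective is non-smooth
  at the prior mode, so these fits use bounded Powell on the unit box,
  which tolerates the kink (an optional smoothing of |·| is deliberately
  not the default).
* **λ sweep**: traced in the homotopy direction — descending from λ_max
  with each fit warm-started from its predecessor, starting at the prior
  mode — so deviations activate in sensitivity order as the penalty
  relaxes. The λ = 0 entry is an independent full multi-start ML fit.
  A final path-consistency pass re-selects, for every λ, the best candidate
  from one shared pool (all path fits, the prior mode, and soft-thresholded
  interpolates of the fitted vectors toward the mode — the exact solution
  path of the orthogonal-design analogue). Because every λ then minimizes
  over the same candidate set, an exchange argument makes D(λ)
  non-increasing and J1(λ) non-decreasing *exactly*, and the pass can only
  improve each fit.
* **Knee selection**: both axes of the (J1, D) curve are min–max
  normalized; the knee is the point of maximum perpendicular distance to
  the chord joining the endpoints, ties toward smaller λ; a numerically
  flat curve in either axis returns the smallest nonzero λ with a
  degeneracy flag. The default grid is {0} ∪ 25 log-spaced points in
  [1e-3, 10]; because λ trades off against a J1 whose scale is σ^-2, the
  grid's upper end should be scaled by 1/σ² when the noise is far from
  nominal (the recovery tests do this).

Optimization budgets (`maxfev`, starts) are constructor arguments; the
study driver's defaults (2 starts / 1000 evaluations for λ=0 fits, 250 per
warm-started sweep point, a {0} ∪ 12-point log-spaced λ grid) are sized so a full 23-subject
three-case leave-one-out study completes in minutes on one core. Larger
budgets sharpen the λ=0 overfitting contrast but do not change the
qualitative orderings.

## Error metrics

e1 (fitted signals) and e2 (withheld signals) use the same grouping: per
subject, a σ-normalized L2 error pooled over the relevant signals inside
one square root, divided by the root of the pooled sample count; the metric
is the mean over subjects. For one subject and one signal this is
RMSE/σ. The typeset definitions this implements are ambiguous about
whether the subject count sits inside the root; the mean-over-subjects
reading is used because it matches the metrics' description as a
"normalized RMSE" and makes e1/e2 invariant to jointly rescaling a signal's
units and its σ. e2 with no withheld signal (case 1) is a defined-empty
result (`None`), never zero. The paired regularized-vs-unregularized
contrasts use the exact two-sided Wilcoxon signed-rank test (normal
approximation with continuity correction above 25 informative pairs), zero
differences dropped, Bonferroni-multiplied by the number of contrasts run.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes: N = 23
sheep-sized subjects; 25 ml/kg hemorrhage spread over minutes 0–15,
5 ml/kg over 50–55 and 70–75; closed-loop MAP-targeted infusion over
30–180 min; all three signals sampled every 5 min with additive Gaussian
noise.

Inter-individual variability is sparse-Laplace: each parameter deviates
with probability 0.3, with Laplace scale 0.15·b_m, clipped to bounds —
instantiating the parameter-compressibility premise the L1 prior encodes.
Baselines: V_B0 ~ N(2.37, 0.44²) L (truncated at 0.9), HR ~ N(90, 8²),
weight ~ U(35, 50) kg; baseline CO is drawn N(4.40, 0.96²) L/min and the
subject's A is anchored (clipped into bounds) so the model equilibrium
reproduces it; MAP_0 equals the subject's MAP_target. Draws that collapse
under the protocol are rejected and resampled (capped). The resuscitation
controller is a deliberately simple stand-in for the closed-loop algorithms
used in the original experiments (which are out of scope): a PI law on the
MAP error, set point 70 mmHg, gains 0.04 / 0.008 ml/kg/min per mmHg, rate
clamped to [0, 2 ml/kg/min], held between 5-min calls, with integral
anti-windup; it sees the noisy MAP.

What passing the calibration shows — and what it does not: the cohort's
population means of BV/CO/MAP at t = 0 and t = 15 sit inside two standard
errors of the published means (using the published SDs), across seeds, with
residual ~5–10% of seeds grazing a band edge exactly as sampling noise of a
23-subject mean predicts. The generator does **not** mimic individual
animals, red-cell/hemoglobin kinetics, urinary output as a separate stream,
measurement-noise heteroscedasticity, or HR dynamics; and under the
stand-in controller the cohort recovers less by t = 180 (BV ≈ 1.9 L,
MAP ≈ 73 mmHg) than the published end-of-resuscitation means — the late
protocol phase is qualitatively, not quantitatively, matched. Conclusions
from synthetic studies therefore transfer to real data only at the level of
orderings and trends, not error magnitudes.

## Study design

For each subject the prior mode is fitted on the other N−1 subjects
(leave-one-out). Because the pooled objective changes little when one
subject is removed, each leave-one-out fit is warm-started from a cached
full-population fit and refined with a reduced budget. Each subject × case
then gets one λ sweep, providing both the λ = 0 fit and the knee-selected
regularized fit; metrics (e1, e2, per-signal RMSE, D, signed per-parameter
deviations) are computed for the population-average, λ = 0, and regularized
variants; e2 contrasts for the withheld-signal cases enter the signed-rank
test with Bonferroni over the contrasts performed. Per-subject failures are
recorded and excluded from aggregates, never silently. The entire study is
reproducible under a fixed seed.

On seeded synthetic cohorts the study reproduces the method's central
qualitative claims: mean D(regularized) < mean D(λ=0) in all three cases;
in case 3 the mean withheld-signal error e2(regularized) < e2(λ=0); and the
per-subject trade-off curves show the expected regime structure (D
non-increasing, J1 non-decreasing, e2 dipping below its λ=0 value before
rising toward the population-average level). The corresponding error
magnitudes on real animal data are not reproducible from synthetic cohorts
and are not claimed.

## Known limitations

* MAP-only fitting (case 3) is genuinely under-determined: without volume
  data, compensating deviations across the cardiovascular-function
  parameters can reproduce MAP almost exactly (the package's motivation for
  regularization, but also a limit on what any fit can recover there).
* The knee rule is one defensible automation of a visual-bend choice;
  near-degenerate trade-off curves make λ* sensitive to the grid.
* Powell with finite budgets under-converges the non-smooth mid-λ fits;
  the path-consistency pass bounds the damage but reported J1/D values at
  mid-λ are upper bounds on the true path.
* The infeasibility penalty creates a plateau that gradient-free searches
  must skirt; pathological bound boxes (far from the calibrated defaults)
  may strand starts on it.
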