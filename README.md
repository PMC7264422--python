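# hemovol

Individualizing a lumped-parameter model of blood-volume kinetics and
cardiovascular hemodynamics under hemorrhage and fluid resuscitation, using
L1-regularized maximum-a-posteriori (MAP) estimation around a
population-average model — with a calibrated virtual-sheep cohort generator
so the whole analysis runs without access to animal data.

## Who this is for

Researchers in computational physiology and critical-care modeling who need
to fit mechanistic hemodynamic models to *scarce* per-subject data (often
only arterial pressure), and want a tested reference implementation of
regularized individualization: population-prior construction, per-subject
L1-penalized fitting, regularization-weight selection, and evaluation of
withheld-signal (internal-state) predictions.

## The model

Three coupled components, driven by external fluid gain `u(t)` and loss
`v(t)` (L/min):

**Volume kinetics** — blood-volume change ΔV_B obeys

    dΔV_B/dt = u − v − u_ex,        u_ex = −K_p (r_BV − ΔV_B),
    r_BV(t) = ∫u/(1+α_u) − ∫v/(1+α_v),

so a fraction 1/(1+α_u) of infused fluid is retained intravascularly and a
fraction 1/(1+α_v) of shed volume is not refilled from the interstitium,
with first-order exchange at rate K_p.

**Cardiac output** — the unique CO > 0 solving the implicit venous-return /
ventricular equilibrium

    CO = HR / (A + (A/E_s)·HR·TPR) · log(1 − (γk/B)·TPR·CO
                                         + (γ/(BC_s))(V_B − η V_B0)),

whose right-hand side is strictly decreasing in CO. Only the lumped ratios
(A, A/E_s, γk/B, γ/(BC_s), η) are parameters.

**Pressure regulation** — MAP = CO·TPR with TPR = TPR_0 + ΔTPR and

    dΔTPR/dt = −p_TPR ΔTPR + k_TPR (MAP_target − MAP).

**Estimation** — with per-signal noise SDs σ and the 11-vector θ bounded in
[θ̌, θ̂] (ranges b = θ̂ − θ̌):

    θ̂_i = argmin  J1(θ) + λ Σ_m |θ_m − θ̄_m| / b_m,
    J1(θ) = Σ_signals Σ_j (model(t_j) − data(t_j))² / σ²,

where θ̄ is the population-average vector (pooled maximum likelihood over
the other subjects, leave-one-out) and λ is chosen per subject at the knee
of the (J1, D) trade-off curve, D = Σ|θ−θ̄|/b. Data-scarcity cases: 1 =
BV+CO+MAP fitted, 2 = CO+MAP, 3 = MAP only; withheld signals score the
internal-state error e2.

## Worked example

```python
import numpy as np
from hemovol import (GeneratorConfig, Prior, default_bounds,
                     generate_population, sweep_lambda)
from hemovol.estimation import PopulationModel

cohort = generate_population(GeneratorConfig(), n=23, seed=1)
records = [s.record for s in cohort]

pop = PopulationModel(n_starts=2, maxfev=1200).fit(records[1:])   # prior from 22
prior = pop.prior()

sweep = sweep_lambda(records[0].with_case(3), prior)   # MAP-only individualization
best = sweep.selected_fit()
print(f"lambda* = {sweep.lambda_star:.3g}")
print(f"J1 = {best.j1:.1f}   D = {best.d:.2f}   (lambda=0: J1 = {sweep.fits[0].j1:.1f}, "
      f"D = {sweep.fits[0].d:.2f})")
```

Output (seed 1):

```
lambda* = 0.215
J1 = 24.5   D = 2.06   (lambda=0: J1 = 24.3, D = 4.39)
```

Reading: the MAP-only maximum-likelihood fit (λ=0) matches 37 MAP samples
at roughly the noise floor (J1 ≈ n) but wanders D ≈ 4.4 range-units from
the population mode; the knee-selected weight keeps essentially the same
goodness of fit while cutting the parametric deviation by half — the
regularization is absorbing only the data-supported individual differences.

The same pipeline end-to-end, from a shell:

```bash
hemovol generate --n 23 --seed 7 --out data/
hemovol study --data data/ --cases 1,2,3 --lam auto --out results/
```

which writes per-case summary tables (per-signal RMSE, e1, e2, D, mean λ*),
per-subject λ-sweep curves, per-parameter deviation tables, and the
Wilcoxon signed-rank p-values for the regularized-vs-unregularized e2
contrasts.

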