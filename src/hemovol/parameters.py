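"""Lumped model parameters, physiological bounds, and the Laplace prior.

The model is parameterized by an 11-element vector of lumped constants.
Several physical constants (systemic capacitance ``C_s``, ventricular
elastance ``E_s``, the pressure-volume shape constant ``B``, the venous
return resistance ratio ``k`` and the central-venous/end-diastolic pressure
proportionality ``gamma``) enter the equations only through fixed ratios, so
only the lumped ratios are represented:

========== =====================================================
name        meaning (units)
========== =====================================================
alpha_u     fluid-gain partition exponent (dimensionless)
alpha_v     fluid-loss partition exponent (dimensionless)
K_p         blood-volume control gain (1/min)
A           pressure-volume shape constant (model units)
A_over_Es   lumped ratio A/E_s (model units)
gk_over_B   lumped ratio gamma*k/B (1/mmHg)
g_over_BCs  lumped ratio gamma/(B*C_s) (1/L)
eta         unstressed-volume fraction (dimensionless, in [0, 1))
k_TPR       MAP-regulation gain (model units)
p_TPR       MAP-regulation rate (1/min)
MAP_target  intrinsic MAP set point (mmHg)
========== =====================================================

Units of the purely lumped constants (``A``, ``A_over_Es``, ``k_TPR``) follow
from dimensional consistency of the cardiac-output equilibrium equation and
are documented rather than enforced.

Default bounds and the default population mode are the package's own
physiological calibration (chosen so that a typical sheep-sized subject has
a baseline equilibrium near BV 2.37 L, CO 4.4 L/min, MAP 91 mmHg); they are
configurable and make no claim to be measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ModelParameters",
    "ParameterBounds",
    "Prior",
    "default_bounds",
    "default_population_mode",
]

#: Canonical ordering of the lumped parameter vector.
PARAM_NAMES: tuple[str, ...] = (
    "alpha_u",
    "alpha_v",
    "K_p",
    "A",
    "A_over_Es",
    "gk_over_B",
    "g_over_BCs",
    "eta",
    "k_TPR",
    "p_TPR",
    "MAP_target",
)

N_PARAMS = len(PARAM_NAMES)


@dataclass(frozen=True)
class ModelParameters:
    """The 11-element lumped parameter vector (canonical order above)."""

    alpha_u: float
    alpha_v: float
    K_p: float
    A: float
    A_over_Es: float
    gk_over_B: float
    g_over_BCs: float
    eta: float
    k_TPR: float
    p_TPR: float
    MAP_target: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("model parameters must be finite")
        for name in ("alpha_u", "alpha_v", "K_p", "p_TPR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 <= self.eta < 1.0):
            raise ValueError(f"eta must lie in [0, 1), got {self.eta}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected shape ({N_PARAMS},), got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "ModelParameters":
        return cls(**{n: float(m[n]) for n in PARAM_NAMES})

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds [lower, upper] for every lumped parameter.

    ``ranges`` (b_m = upper_m - lower_m) normalizes parameter deviations in
    the L1 prior and in the deviation distance D.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (N_PARAMS,) or hi.shape != (N_PARAMS,):
            raise ValueError(f"bounds must have shape ({N_PARAMS},)")
        if not np.all(hi > lo):
            bad = [PARAM_NAMES[i] for i in np.nonzero(hi <= lo)[0]]
            raise ValueError(f"upper must exceed lower for all parameters: {bad}")

    @property
    def ranges(self) -> np.ndarray:
        """b_m = upper_m - lower_m (> 0 elementwise)."""
        return self.upper - self.lower

    def contains(self, theta: ModelParameters | np.ndarray, atol: float = 1e-12) -> bool:
        arr = theta.to_array() if isinstance(theta, ModelParameters) else np.asarray(theta)
        return bool(np.all(arr >= self.lower - atol) and np.all(arr <= self.upper + atol))

    def clip(self, arr: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(arr, dtype=float), self.lower, self.upper)

    def normalize(self, arr: np.ndarray) -> np.ndarray:
        """Map parameter values to the unit box [0, 1]^11."""
        return (np.asarray(arr, dtype=float) - self.lower) / self.ranges

    def denormalize(self, unit: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(unit, dtype=float) * self.ranges

    @classmethod
    def from_mapping(cls, m: Mapping[str, tuple[float, float]]) -> "ParameterBounds":
        lo = np.array([m[n][0] for n in PARAM_NAMES], dtype=float)
        hi = np.array([m[n][1] for n in PARAM_NAMES], dtype=float)
        return cls(lo, hi)

    def to_dict(self) -> dict[str, tuple[float, float]]:
        return {
            n: (float(self.lower[i]), float(self.upper[i]))
            for i, n in enumerate(PARAM_NAMES)
        }


# Default physiological ranges. Not measured values: a documented, editable
# calibration wide enough to cover plausible ovine physiology around the
# default population mode below.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_u": (1.0, 6.0),
    "alpha_v": (0.25, 3.5),
    "K_p": (0.05, 0.8),
    "A": (10.0, 40.0),
    "A_over_Es": (0.0005, 0.006),
    "gk_over_B": (0.001, 0.01),
    "g_over_BCs": (1.0, 6.0),
    "eta": (0.35, 0.8),
    "k_TPR": (0.005, 0.1),
    "p_TPR": (0.02, 0.3),
    "MAP_target": (70.0, 110.0),
}

# Population mode used both as the generator's center and as the default
# optimizer start.  Chosen (once) so that the closed-form baseline
# equilibrium at V_B0 = 2.37 L, HR = 90 bpm gives CO ~ 4.4 L/min and
# MAP ~ 91.2 mmHg, and a 25 ml/kg hemorrhage over 15 min lands near the
# post-hemorrhage population means.
_DEFAULT_MODE: dict[str, float] = {
    "alpha_u": 3.0,
    "alpha_v": 1.8,
    "K_p": 0.25,
    "A": 22.18,
    "A_over_Es": 0.002,
    "gk_over_B": 0.004,
    "g_over_BCs": 3.0,
    "eta": 0.59,
    "k_TPR": 0.015,
    "p_TPR": 0.1,
    "MAP_target": 91.22,
}


def default_bounds() -> ParameterBounds:
    """Package-default parameter box (see module docstring on provenance)."""
    return ParameterBounds.from_mapping(_DEFAULT_BOUNDS)


def default_population_mode() -> ModelParameters:
    """Package-default population-mode parameter vector."""
    return ModelParameters.from_mapping(_DEFAULT_MODE)


@dataclass(frozen=True)
class Prior:
    """Laplace (L1) prior around a population mode.

    The negative log prior contributes J2(theta) = lam * sum_m
    |theta_m - theta_bar_m| / b_m with b_m the bound ranges; lam = 0
    removes the prior (pure maximum likelihood).
    """

    theta_bar: ModelParameters
    bounds: ParameterBounds = field(default_factory=default_bounds)
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if not self.bounds.contains(self.theta_bar):
            raise ValueError("theta_bar must lie within the bounds")

    def with_lambda(self, lam: float) -> "Prior":
        return Prior(self.theta_bar, self.bounds, lam)
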