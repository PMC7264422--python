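"""Shared fixtures: default model pieces and a small session-scoped cohort."""

from __future__ import annotations

import numpy as np
import pytest

from hemovol import (
    GeneratorConfig,
    InputSchedule,
    NoiseModel,
    Segment,
    SubjectContext,
    baseline_equilibrium,
    default_bounds,
    default_population_mode,
    generate_population,
)


@pytest.fixture(scope="session")
def mode_params():
    return default_population_mode()


@pytest.fixture(scope="session")
def bounds():
    return default_bounds()


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def baseline_context(mode_params):
    """A 40 kg subject resting exactly on the model equilibrium."""
    co0, map0 = baseline_equilibrium(mode_params, v_b0=2.37, hr=90.0)
    return SubjectContext(V_B0=2.37, CO_0=co0, MAP_0=map0, body_weight=40.0, HR=90.0)


@pytest.fixture(scope="session")
def hemorrhage_schedule():
    """25 ml/kg initial bleed at 40 kg: 1.0 L over minutes 0-15."""
    return InputSchedule([Segment(0.0, 15.0, 0.0, 1.0 / 15.0)], horizon=180.0)


@pytest.fixture(scope="session")
def sampling_grid():
    return np.arange(0.0, 181.0, 5.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six virtual subjects under the full closed-loop protocol."""
    return generate_population(GeneratorConfig(), n=6, seed=11)
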