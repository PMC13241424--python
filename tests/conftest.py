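import numpy as np
import pytest

from screenbias import (
    SimulationConfig,
    apply_criteria,
    assign_conditions,
    default_criteria,
    inject_treatment_effect,
    simulate_population,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(master_seed=0)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study for fast pipeline tests: 400 students, 20 classrooms."""
    return SimulationConfig(
        n_students=400, n_classrooms=20, class_size=20, n_reps=25, master_seed=0
    )


@pytest.fixture(scope="session")
def default_population(default_config):
    """One fully prepared default population (seed 0) with the three criteria."""
    ss = np.random.SeedSequence(default_config.master_seed).spawn(1)[0]
    pop, assign, effect = ss.spawn(3)
    table = simulate_population(default_config, pop)
    table = assign_conditions(table, assign)
    table = inject_treatment_effect(
        table, default_config.effect_mean, default_config.effect_sd, effect
    )
    return apply_criteria(table, default_criteria())
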