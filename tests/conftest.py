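import numpy as np
import pytest

from fermkin import SCENARIO_NAMES, SimulationSpec, builtin_scenario, simulate


@pytest.fixture(scope="session")
def scenarios():
    return {name: builtin_scenario(name) for name in SCENARIO_NAMES}


@pytest.fixture(scope="session")
def clean_daily(scenarios):
    """Noise-free daily (0-5 d) trajectories for each built-in strain."""
    out = {}
    for name, sc in scenarios.items():
        out[name] = simulate(
            SimulationSpec(sc.initial, sc.params, sc.sample_times), label=name
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
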