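import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ovct import DEFAULT_INITIAL_STATE, ParameterSet, TreatmentSchedule, simulate


@pytest.fixture(scope="session")
def baseline():
    return ParameterSet()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230203)


def random_states_and_params(rng, n):
    """Random positive states and parameter perturbations for oracle checks."""
    baseline = ParameterSet()
    draws = []
    for _ in range(n):
        state = rng.uniform(0.0, 1.0, size=9) * np.array(
            [1e9, 1e8, 1e8, 1e4, 1e4, 1e6, 1e6, 1e4, 1e5])
        factors = rng.uniform(0.5, 2.0, size=len(baseline.as_dict()))
        params = ParameterSet(**{
            k: v * f for (k, v), f in zip(baseline.as_dict().items(), factors)})
        draws.append((state, params))
    return draws


@pytest.fixture(scope="session")
def mock_trajectory(baseline):
    """Untreated run, day 8 to 18, at default solver settings."""
    return simulate(baseline, TreatmentSchedule(0.0, 0.0),
                    DEFAULT_INITIAL_STATE, 8.0, 18.0)


@pytest.fixture(scope="session")
def combo_trajectory(baseline):
    """Combined-therapy run (s=2e6, u=0.76), day 8 to 30."""
    return simulate(baseline, TreatmentSchedule(2e6, 0.76),
                    DEFAULT_INITIAL_STATE, 8.0, 30.0)
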