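import numpy as np
import pandas as pd
import pytest

from crossage.synthgen import CohortData, ScenarioTable, SimParams1, gen_example1


@pytest.fixture(scope="session")
def example1_small() -> CohortData:
    return gen_example1(SimParams1(n=400, seed=123))


@pytest.fixture(scope="session")
def example1_large() -> CohortData:
    return gen_example1(SimParams1(n=100_000, seed=2024))


@pytest.fixture()
def scenario_table() -> ScenarioTable:
    return ScenarioTable(seed=7)


@pytest.fixture()
def tiny_cohort() -> CohortData:
    """10 subjects, 2 markers; small enough for brute-force oracles."""
    rng = np.random.default_rng(99)
    age = rng.normal(50, 5, 10)
    markers = pd.DataFrame(
        {
            "m1": 0.5 * age + rng.normal(0, 1, 10),
            "m2": -0.3 * age + rng.normal(0, 2, 10),
        }
    )
    return CohortData(age=age, markers=markers)
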