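import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmburden import (
    DisabilityWeight,
    DisabilityWeightSet,
    RunConfig,
    load_fixture_tables,
    make_synthetic_life_table,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def table(fixture_tables):
    return fixture_tables[0]


@pytest.fixture(scope="session")
def incidence(fixture_tables):
    return fixture_tables[1]


@pytest.fixture(scope="session")
def life_table():
    return make_synthetic_life_table()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def dw():
    return DisabilityWeightSet()


@pytest.fixture(scope="session")
def dw_with_bounds():
    return DisabilityWeightSet(
        uncomplicated=DisabilityWeight(0.334, 0.30, 0.37),
        complicated=DisabilityWeight(0.663, 0.60, 0.72),
    )


@pytest.fixture(scope="session")
def burden_result(table, incidence, dw_with_bounds, life_table, config):
    from dmburden import compute_burden
    from dmburden.burden import WHOLE_POPULATION_2016

    return compute_burden(
        table, incidence, dw_with_bounds, life_table, config,
        whole_population=WHOLE_POPULATION_2016,
    )


def random_transition_table(rng: np.random.Generator):
    """A valid random TransitionTable (exit sums kept below 1)."""
    import pandas as pd

    from dmburden import AGE_GROUP_LABELS, TransitionTable
    from dmburden.states import TRANSITION_COLUMNS

    idx = pd.MultiIndex.from_product(
        [["male", "female"], AGE_GROUP_LABELS], names=["sex", "age_group"]
    )
    df = pd.DataFrame(
        rng.uniform(0.0, 0.3, size=(len(idx), len(TRANSITION_COLUMNS))),
        index=idx,
        columns=TRANSITION_COLUMNS,
    )
    return TransitionTable(df)
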