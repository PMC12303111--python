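import numpy as np
import pandas as pd
import pytest

from burplan import DeploymentWindow
from burplan.synthetic import LogScenario, RetentionScenario, gen_interaction_log


@pytest.fixture
def badger_table():
    # early: 27 of 36 passed; late: 30 of 35
    return [[27, 9], [30, 5]]


@pytest.fixture
def fox_table():
    # early: 43 of 74 passed; late: 51 of 66
    return [[43, 31], [51, 15]]


@pytest.fixture
def window_11d():
    return DeploymentWindow("site3", "2022-06-01 00:00:00", "2022-06-12 00:00:00")


@pytest.fixture
def small_log():
    """A small single-species interaction log with deterministic seed."""
    scenario = LogScenario(
        site_presence={"site3": 19 / 264},
        species_mix={"badger": 1.0},
        window_hours=264,
        seed=11,
    )
    return gen_interaction_log(scenario)


@pytest.fixture
def retention_scenario():
    return RetentionScenario(n=500, seed=7)
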