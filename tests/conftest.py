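import numpy as np
import pytest

from crcsim import (Individual, LifeTable, NaturalHistoryParams,
                    default_life_tables)
from crcsim.tables import TERMINAL_AGE


@pytest.fixture(scope="session")
def life_tables():
    return default_life_tables()


@pytest.fixture(scope="session")
def immortal_life_table():
    """No other-cause mortality until the terminal age."""
    q = np.zeros(TERMINAL_AGE + 1)
    q[TERMINAL_AGE] = 1.0
    return {sex: LifeTable(sex, q.copy()) for sex in ("male", "female")}


@pytest.fixture
def default_params():
    return NaturalHistoryParams()


def make_individual(pid=0, sex="male", birth_year=1950, death_age=95.0,
                    risk=1.0, first_invitation_year=None):
    return Individual(pid, sex, birth_year, death_age, risk,
                      first_invitation_year)


@pytest.fixture
def person():
    return make_individual()
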