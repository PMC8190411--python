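import numpy as np
import pandas as pd
import pytest

import dietrrr as d


@pytest.fixture(scope="session")
def small_cohort():
    """A default female stratum small enough for fast unit tests."""
    spec = d.default_spec("female", n_participants=300, seed=7)
    return d.generate_cohort(spec)


@pytest.fixture(scope="session")
def screened_stratum(small_cohort):
    df, truth = small_cohort
    kept, log = d.apply_inclusion_filters(df)
    return kept, log, truth


def make_day_matrices(values_by_person):
    """Build (day1, day2) single-group frames from [(d1, d2), ...] pairs."""
    d1 = pd.DataFrame({"G1": [v[0] for v in values_by_person]})
    d2 = pd.DataFrame({"G1": [v[1] for v in values_by_person]})
    return d1, d2


@pytest.fixture
def rng():
    return np.random.default_rng(42)
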