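import numpy as np
import pytest

import sealsimm as ss
from sealsimm import tables


@pytest.fixture(scope="session")
def prey_summaries():
    return tables.prey_summaries()


@pytest.fixture(scope="session")
def three_groups(prey_summaries):
    scheme = ss.load_groupings()["three_source"]
    return ss.pool_group_stats(prey_summaries, scheme)


@pytest.fixture(scope="session")
def six_groups(prey_summaries):
    return ss.pool_group_stats(prey_summaries, ss.ward_cluster(prey_summaries, 6))


@pytest.fixture(scope="session")
def post_tef_vib():
    return tables.post_tef("vibrissae")


@pytest.fixture(scope="session")
def vib_consumers():
    return ss.matched_consumers("vibrissae", seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
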