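import numpy as np
import pytest

from ampmock.pipeline import make_external_db
from ampmock.simulate import (SimParams, make_contaminants, make_mock_strains,
                              simulate_pcr, standard_communities)


@pytest.fixture(scope="session")
def strains():
    return make_mock_strains(seed=0)


@pytest.fixture(scope="session")
def mock_refs(strains):
    return {s.strain_id: s.v4_seq for s in strains if s.v4_seq}


@pytest.fixture(scope="session")
def communities(strains):
    return standard_communities(strains)


@pytest.fixture(scope="session")
def contaminants(strains):
    return make_contaminants(8, seed=1, mock_strains=strains)


@pytest.fixture(scope="session")
def external_db(strains):
    return make_external_db(strains, seed=2)


@pytest.fixture(scope="session")
def clean_chimeric_pool(communities):
    """Noise-free PCR pool with a substantial chimera fraction."""
    params = SimParams(cycles_step1=20, cycles_step2=0, pol_error_rate=0.0,
                       incomplete_ext_prob=0.06, seed=11)
    return simulate_pcr(communities["Bm1"], params, 1000,
                        rng=np.random.default_rng(11))


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet)) for _ in range(n))
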