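import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from defaunasim import SynthConfig, generate, two_wsg_toy
from defaunasim.classification import DispersalGroup

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_community():
    """A 60-species / 3,000-stem synthetic plot with the default WSG shift."""
    return generate(SynthConfig(n_species=60, n_stems=3000, seed=11))


@pytest.fixture(scope="session")
def null_community():
    """Same size but delta_wsg = 0: guild labels carry no WSG signal."""
    return generate(SynthConfig(n_species=60, n_stems=3000, delta_wsg=0.0, seed=11))


@pytest.fixture()
def toy():
    """Two-species single-dbh community with analytic swap outcome."""
    return two_wsg_toy(n_target=10, n_pool=10, w_l=0.8, w_o=0.6, dbh=10.0)


@pytest.fixture()
def traits_row():
    def make(*groups):
        return frozenset(DispersalGroup(g) for g in groups)

    return make


@pytest.fixture()
def census_csv(tmp_path):
    path = tmp_path / "census.csv"
    pd.DataFrame(
        {
            "tag": ["T1", "T2", "T3"],
            "species": ["SP1", "SP1", "SP2"],
            "dbh": [5.0, 12.5, 47.0],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
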