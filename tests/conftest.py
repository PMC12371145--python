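import numpy as np
import pandas as pd
import pytest

import windmate as wm
from windmate.msatgen import LocusModel


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions (3 x 61 plants)."""
    return wm.run_all(wm.RunConfig(), seed=7)


@pytest.fixture(scope="session")
def default_plants(default_run):
    return default_run["plants"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def biallelic_locus():
    return LocusModel("La", [100, 102], [0.5, 0.5])


def make_plants(rows):
    """Small plants table from (plant_id, x, y, nf, nm) tuples, one population."""
    df = pd.DataFrame(rows, columns=["plant_id", "x_cm", "y_cm", "nf", "nm"])
    df["population_id"] = "P1"
    df["size_log"] = 3.0
    df["biomass_g"] = np.exp(3.0)
    return df
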