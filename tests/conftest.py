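import numpy as np
import pandas as pd
import pytest

from forestbef.config import RunConfig
from forestbef.io import TRAIT_COLUMNS, validate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_inventory():
    """Two plots, three species, hand-countable stems."""
    rows = [
        ("p1", "AM", "upper", "oak", 10.0, 8.0),
        ("p1", "AM", "upper", "oak", 12.0, 9.0),
        ("p1", "AM", "upper", "oak", 8.0, 7.0),
        ("p1", "AM", "upper", "pine", 15.0, 11.0),
        ("p2", "AM", "middle", "pine", 9.0, 8.5),
        ("p2", "AM", "middle", "fir", 11.0, 10.0),
    ]
    df = pd.DataFrame(
        rows, columns=["plot_id", "plantation", "slope", "species", "dbh", "height"]
    )
    df["dbh_basis"] = "breast_height"
    return df


@pytest.fixture
def tiny_traits():
    rng = np.random.default_rng(7)
    data = {t: rng.uniform(1.0, 10.0, 3) for t in TRAIT_COLUMNS}
    return pd.DataFrame(data, index=pd.Index(["oak", "pine", "fir"], name="species"))


@pytest.fixture
def tiny_soil():
    return pd.DataFrame(
        {"soc": [12.0, 14.0], "tn": [1.1, 1.3], "tp": [0.4, 0.5], "tk": [9.0, 8.0]},
        index=pd.Index(["p1", "p2"], name="plot_id"),
    )


@pytest.fixture
def tiny_params():
    return pd.DataFrame(
        {"a": [0.05, 0.06, 0.07], "b": [0.9, 0.88, 0.92]},
        index=pd.Index(["oak", "pine", "fir"], name="applies_to"),
    )


@pytest.fixture
def tiny_dataset(tiny_inventory, tiny_traits, tiny_soil):
    return validate_dataset(tiny_inventory, tiny_traits, tiny_soil, RunConfig())


@pytest.fixture(scope="session")
def community():
    """One simulated 36-plot community dataset, shared across tests."""
    from forestbef import synthetic

    rng = np.random.default_rng(99)
    return synthetic.gen_community(synthetic.CommunityGenSpec(), rng)
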