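import numpy as np
import pandas as pd
import pytest

import betascale as bs


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def small_community(rng):
    """A 12-grain x 5-species abundance table with no empty grains."""
    X = rng.integers(1, 25, size=(12, 5)).astype(float)
    return pd.DataFrame(X, columns=[f"sp{j}" for j in range(5)]).rename_axis("grain")


@pytest.fixture
def tiny_stem_map():
    stems = pd.DataFrame(
        {
            "x": [0.0, 5.0, 25.0, 199.0],
            "y": [0.0, 5.0, 30.0, 150.0],
            "species": ["A", "A", "B", "C"],
            "dbh": [2.0, 10.0, 1.0, 33.5],
        }
    )
    return bs.StemMap(260.0, 200.0, stems)


@pytest.fixture(scope="session")
def mixed_scenario():
    """One canonical synthetic plot reused by several integration tests."""
    env, stem_map = bs.scenario("mixed", seed=11)
    return env, stem_map, env.sample_table()
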