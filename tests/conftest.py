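import numpy as np
import pandas as pd
import pytest

from standstruct.simulate import StandSpec, generate_stand


@pytest.fixture(scope="session")
def poisson_stand() -> pd.DataFrame:
    """A 200-tree random stand reused by several suites."""
    return generate_stand(StandSpec(n_trees=200, pattern="poisson", seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_stand(xy, dbh=None, species=None) -> pd.DataFrame:
    """Hand-built stand table from explicit positions."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "species": species if species is not None else ["sp01"] * n,
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "dbh_cm": dbh if dbh is not None else np.full(n, 20.0),
            "height_m": np.full(n, 10.0),
        }
    )
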