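import numpy as np
import pandas as pd
import pytest

from micellocalc import (
    bundled_compounds,
    bundled_partition_table,
    micelle_registry,
)


@pytest.fixture(scope="session")
def registry():
    return micelle_registry()


@pytest.fixture(scope="session")
def experimental_table():
    return bundled_partition_table()


@pytest.fixture(scope="session")
def compounds():
    return bundled_compounds()


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r on pairwise-complete observations.

    Independent of pandas/scipy correlation routines: sums of squares
    computed directly from the definition.
    """
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    xbar, ybar = x.mean(), y.mean()
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    sxx = float(np.sum((x - xbar) ** 2))
    syy = float(np.sum((y - ybar) ** 2))
    return sxy / np.sqrt(sxx * syy)


@pytest.fixture(scope="session")
def compound_csv(tmp_path_factory):
    path = tmp_path_factory.mktemp("data") / "compounds.csv"
    pd.DataFrame(
        {
            "name": ["Phenol", "Aniline", "Pyridine"],
            "smiles": ["Oc1ccccc1", "Nc1ccccc1", "c1ccncc1"],
            "tags": ["phenol", "aniline", "azine"],
        }
    ).to_csv(path, index=False)
    return path
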