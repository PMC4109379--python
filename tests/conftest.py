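import warnings

import numpy as np
import pandas as pd
import pytest

from famgut import (
    CountTable,
    FamilyConfig,
    distance_matrix,
    generate_family,
    rarefy,
    to_relabund,
)


@pytest.fixture(scope="session")
def family():
    """One deterministic synthetic household shared across tests."""
    table, meta, truth = generate_family(FamilyConfig(seed=42))
    return table, meta, truth


@pytest.fixture(scope="session")
def family_rel(family):
    """Rarefied relative abundances of the session household."""
    table, meta, truth = family
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rel = to_relabund(rarefy(table, 1827, seed=7))
    return rel


@pytest.fixture(scope="session")
def family_dist(family):
    """Subsample-averaged theta-YC distances of the session household."""
    table, meta, truth = family
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return distance_matrix(table, depth=1827, iters=10, seed=11)


@pytest.fixture
def tiny_table():
    data = pd.DataFrame(
        [[5, 3, 2], [1, 0, 9]],
        index=pd.Index(["s1", "s2"], name="Group"),
        columns=["Otu001", "Otu002", "Otu003"],
    )
    return CountTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
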