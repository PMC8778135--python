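import io

import numpy as np
import pandas as pd
import pytest

from microconfound.data_model import (
    CountTable, MetadataFrame, TaxonomyTable, read_tree,
)
from microconfound.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture
def toy_counts() -> CountTable:
    return CountTable(pd.DataFrame(
        [[3, 1, 0], [1, 0, 2], [5, 5, 5], [0, 2, 8]],
        index=["t1", "t2", "t3", "t4"], columns=["A", "B", "C"]))


@pytest.fixture
def toy_meta() -> MetadataFrame:
    df = pd.DataFrame(
        {"group": ["HC", "HC", "CD", "CD", "UC", "UC"],
         "age": [30.0, 41.0, 55.0, 62.0, 47.0, 39.0],
         "cereals": ["yes", "no", "no", "no", "yes", "no"]},
        index=[f"S{i}" for i in range(6)])
    return MetadataFrame(df, {"group": "categorical", "age": "numeric",
                              "cereals": "categorical"}, target="group")


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(pd.DataFrame(
        {"kingdom": ["k__B"] * 4,
         "phylum": ["p__X", "p__X", "p__Y", "p__Y"],
         "family": ["f__F1", "f__F1", "f__F2", ""]},
        index=["t1", "t2", "t3", "t4"]))


@pytest.fixture
def four_tip_tree():
    return read_tree(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 3 x 20-sample cohort shared across tests."""
    cfg = SyntheticConfig.confounded(n_per_group=20, n_taxa=10, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
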