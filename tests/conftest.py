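import numpy as np
import pandas as pd
import pytest

import prnet
from prnet.data import Schema, VariableSpec, encode_dataframe


@pytest.fixture
def mixed_schema() -> Schema:
    return Schema(
        [
            VariableSpec("age", "continuous", units="yrs"),
            VariableSpec("creatinine", "continuous", units="umol/l"),
            VariableSpec("ventilator", "binary"),
            VariableSpec("diagnosis", "categorical",
                         categories=("ICM", "NICM", "Other")),
        ],
        outcome="death",
        strata="era",
    )


@pytest.fixture
def mixed_df() -> pd.DataFrame:
    return pd.DataFrame({
        "age": [50.0, 61.0, 43.0, 55.0, 47.0, 66.0],
        "creatinine": [100.0, 140.0, np.nan, 95.0, 120.0, 180.0],
        "ventilator": [0, 0, 1, 0, 0, 1],
        "diagnosis": ["ICM", "NICM", "NICM", "Other", "ICM", "NICM"],
        "death": [0, 1, 0, 0, 0, 1],
        "era": [0, 0, 0, 1, 1, 1],
    })


@pytest.fixture
def mixed_table(mixed_df, mixed_schema):
    return encode_dataframe(mixed_df, mixed_schema)


@pytest.fixture(scope="session")
def small_fit():
    """One modest end-to-end fit shared by interpretation-level tests."""
    spec = prnet.registry_preset(n=6000, seed=77)
    table, _ = prnet.generate(spec)
    results = prnet.PartialResponseNetwork(table).fit(seed=31)
    return spec, table, results
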