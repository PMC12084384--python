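import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nctd.io_tabular import ColumnSchema, TabularDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def mixed_csv(tmp_path):
    """Small CSV with one numeric and one categorical feature plus labels."""
    path = tmp_path / "mixed.csv"
    path.write_text(
        "age,sex,y\n"
        "34,F,0\n"
        "51,M,1\n"
        "29,F,0\n"
    )
    return path


@pytest.fixture
def tiny_numeric_dataset():
    """Hand-written 2x3 all-numeric table used by end-to-end tests."""
    values = pd.DataFrame(
        {"a": [1.0, 3.0], "b": [10.0, 30.0], "c": [100.0, 50.0]}
    )
    schema = [
        ColumnSchema("a", "numeric"),
        ColumnSchema("b", "numeric"),
        ColumnSchema("c", "numeric"),
    ]
    return TabularDataset(values, np.array(["0", "1"]), schema, name="tiny")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
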