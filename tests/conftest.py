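import numpy as np
import pandas as pd
import pytest

from mixclust.mixedio import MixedDataset, VariableSpec


@pytest.fixture
def toy_mixed_dataset() -> MixedDataset:
    """3 samples x 3 variables, one of each scale family."""
    frame = pd.DataFrame(
        {
            "age": [1.0, 3.0, 5.0],
            "grade": ["L", "M", "H"],
            "arm": ["A", "B", "A"],
        },
        index=["s1", "s2", "s3"],
    )
    specs = [
        VariableSpec(name="age", scale="quantitative"),
        VariableSpec(name="grade", scale="ordinal", levels=("L", "M", "H")),
        VariableSpec(name="arm", scale="nominal"),
    ]
    return MixedDataset(frame, specs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)


def make_dataset(columns: dict, specs: list[VariableSpec]) -> MixedDataset:
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame(columns, index=[f"s{i + 1}" for i in range(n)])
    return MixedDataset(frame, specs)
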