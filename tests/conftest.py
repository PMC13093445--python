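import numpy as np
import pandas as pd
import pytest

from thorbfnn.trait_io import CATEGORICAL, CONTINUOUS, TraitTable


def make_table(columns: dict, kinds: dict | None = None) -> TraitTable:
    """Build a TraitTable from plain column dicts; None marks missing cells."""
    df = pd.DataFrame({k: pd.Series(v) for k, v in columns.items()})
    if kinds is None:
        kinds = {}
        for c in df.columns:
            numeric = pd.to_numeric(df[c].dropna(), errors="coerce")
            kinds[c] = CONTINUOUS if numeric.notna().all() else CATEGORICAL
    return TraitTable(data=df, column_kinds=kinds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return make_table(
        {
            "Wing.Length": [100.0, 110.0, None, 95.0, 105.0],
            "Mass": [20.0, 22.0, 19.0, None, 21.0],
            "Tarsus.Length": [25.0, 26.0, 24.0, 23.0, None],
            "Species": ["sparrow", "crow", "sparrow", "tit", "crow"],
            "Sex": ["M", "F", "M", "F", None],
        }
    )


@pytest.fixture(scope="session")
def synthetic_pair():
    """A mid-sized masked synthetic table shared across slow tests."""
    from thorbfnn.synthetic_data import SyntheticConfig, simulate

    cfg = SyntheticConfig(
        n_species=40,
        individuals_per_species=50,
        missing_rates={"Wing.Length": 0.3},
        mechanism="MCAR",
        seed=7,
    )
    return cfg, simulate(cfg)
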