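"""Shared fixtures: small synthetic datasets generated at test time."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from crossdiv import SyntheticConfig, generate_divergence_tables, standardize_table


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Default parameter table at a small gene count (fast, still >= 1/0.025)."""
    return replace(SyntheticConfig(), genes_per_taxon=200, seed=42)


@pytest.fixture(scope="session")
def small_raw_table(small_config) -> pd.DataFrame:
    tables = generate_divergence_tables(small_config)
    return pd.concat(tables.values(), ignore_index=True)


@pytest.fixture(scope="session")
def small_std_table(small_raw_table) -> pd.DataFrame:
    return standardize_table(small_raw_table, granularity="pooled")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
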