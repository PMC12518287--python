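import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from digeflow import io, simulate, spotstats

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def design():
    return simulate.default_design("shoot")


@pytest.fixture
def two_sample_sheet():
    return io.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s_c1", "s_a1"],
                "organ": ["shoot", "shoot"],
                "condition": ["control", "anoxia"],
                "replicate": [1, 1],
                "gel_id": ["g1", "g1"],
            }
        )
    )


@pytest.fixture
def null_log2_table(design):
    """A normalized-scale table with no condition effect."""
    rng = np.random.default_rng(42)
    n = 50
    return io.SpotTable(
        spot_ids=[f"SSP{i:03d}" for i in range(n)],
        matrix=rng.normal(10.0, 0.5, size=(n, len(design))),
        sheet=design,
        log_transformed=True,
        normalized=True,
    )


@pytest.fixture
def planted_table(design):
    table, truth = simulate.generate_spot_table(20, design, seed=7)
    return table, truth


@pytest.fixture
def normalized_planted(planted_table):
    table, truth = planted_table
    return spotstats.quantile_normalize(spotstats.log2_and_average(table)), truth
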