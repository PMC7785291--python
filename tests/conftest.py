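import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_psm_table() -> pd.DataFrame:
    """Two bait runs and two control runs over three proteins."""
    rows = [
        ("expt1", "baitX", "A", 30),
        ("expt1", "baitX", "B", 5),
        ("expt1", "baitX", "C", 5),
        ("ctrl1", "GFP", "A", 3),
        ("ctrl1", "GFP", "B", 2),
        ("ctrl1", "GFP", "C", 15),
        ("ctrl2", "GFP", "A", 2),
        ("ctrl2", "GFP", "B", 3),
        ("ctrl2", "GFP", "C", 15),
    ]
    return pd.DataFrame(
        rows, columns=["run_id", "bait_label", "protein_id", "psm_count"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
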