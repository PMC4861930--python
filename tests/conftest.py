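import numpy as np
import pandas as pd
import pytest

from wsppq import DesignConfig, QuantTable, SimConfig, generate, run_wspp
from wsppq.simulate import make_fixture

CHANNELS = ["113", "114", "115", "116", "117", "118", "119", "121"]
CHANNEL_MAP = {
    "113": "G1", "114": "G1", "115": "G2", "116": "G2",
    "117": "G3", "118": "G3", "119": "G4", "121": "G4",
}


@pytest.fixture(scope="session")
def design():
    return DesignConfig(channel_map=dict(CHANNEL_MAP),
                        comparisons=[("G2", "G1")])


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny_3x3")


@pytest.fixture(scope="session")
def null_dataset():
    """One medium null simulation shared across read-only tests."""
    return make_fixture("null_medium", seed=11)


@pytest.fixture(scope="session")
def null_result(null_dataset):
    ds = null_dataset
    return run_wspp(ds.table, ds.design, ("G2", "G1"), ds.exclusions)


@pytest.fixture
def small_table(design):
    """Hand-sized PSM table: 3 records, 8 channels, simple ratios."""
    rows = []
    for i, e in enumerate([0.0, 1.0, -1.0]):
        row = {"spectrum_id": f"s{i}", "peptide_key": f"PEPK{i}/2",
               "protein_id": f"P{i}"}
        for ch in CHANNELS:
            row[ch] = 1000.0 * 2.0 ** e if CHANNEL_MAP[ch] == "G2" else 1000.0
        rows.append(row)
    return QuantTable(pd.DataFrame(rows), CHANNELS)
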