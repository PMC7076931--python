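import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sadnet.io_tables import OTUTable
from sadnet import synthetic


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 1], [2, 7, 0, 1], [0, 4, 6, 2], [1, 1, 1, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["otuA", "otuB", "otuC", "otuD"])
    meta = pd.DataFrame({
        "site": ["X", "X", "Y", "Y"],
        "region": ["R1", "R1", "R2", "R2"],
        "domain": ["bacteria"] * 4,
    }, index=counts.index)
    return OTUTable(counts, meta)


@pytest.fixture(scope="session")
def tiny_fixture_config():
    return synthetic.FixtureConfig(
        seed=7,
        samples_per_site={"bacteria": 3, "eukarya": 2, "archaea": 2},
        depths={"bacteria": 1500, "eukarya": 400, "archaea": 600},
        richness={"bacteria": 150, "eukarya": 50, "archaea": 30},
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_fixture_config):
    return synthetic.make_fixture(tiny_fixture_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
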