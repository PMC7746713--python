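import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ceranet.io import ExpressionPanel
from ceranet.simulate import FixtureConfig, PlantedSignal, default_config, generate


@pytest.fixture(scope="session")
def small_config():
    """A reduced planted-sponge setup for fast unit tests."""
    return FixtureConfig(
        seed=11,
        n_tissues=4,
        n_circ=40,
        n_mir=15,
        n_gene=120,
        n_sets=8,
        set_size=12,
        planted=[
            PlantedSignal(
                circ_id="circ_0001",
                mir_ids=["mir_0001", "mir_0002"],
                target_set_name="set_01",
            )
        ],
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def fitted_results(small_bundle):
    from ceranet.model import CeRNANetwork

    return CeRNANetwork.from_fixture_bundle(small_bundle).fit()


@pytest.fixture
def panel_3x2():
    values = pd.DataFrame(
        [[1.0, 0.0], [2.0, 5.0], [3.0, 0.0]],
        index=["f1", "f2", "f3"],
        columns=["tA", "tB"],
    )
    return ExpressionPanel(values=values, feature_class="gene", unit_label="CPM")
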