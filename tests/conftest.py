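import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import rsalign as ra

DIAGONAL_MAP = {"17": 1, "18": 2, "19": 4, "37": 6, "20": 7}


@pytest.fixture(scope="session")
def hierarchy():
    """Default structured layer hierarchy, 100 stimuli."""
    return ra.make_layer_hierarchy(n_stimuli=100, seed=11)


@pytest.fixture(scope="session")
def planted(hierarchy):
    """Plan + truth + scalar responses with the diagonal area -> layer map."""
    plan, truth = ra.make_probe_plan(
        DIAGONAL_MAP, probes_per_area=10, snr=10.0, seed=12
    )
    responses = ra.simulate_band_responses(hierarchy, plan, seed=13)
    return plan, truth, responses


@pytest.fixture(scope="session")
def layer_bank(hierarchy):
    from rsalign.mapping import _LayerRDMBank

    return _LayerRDMBank.from_layers(hierarchy)


@pytest.fixture(scope="session")
def planted_mapping(planted, layer_bank, hierarchy):
    plan, truth, responses = planted
    return ra.map_probes(
        responses,
        layer_bank,
        plan,
        n_perm=1000,
        alpha=0.001,
        seed=14,
        layer_names=hierarchy.layer_names,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
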