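import numpy as np
import pandas as pd
import pytest

import phyloexpr as px


@pytest.fixture(scope="session")
def tree33():
    """33-tip pure-birth tree, depth 1 — the emulated study's shape."""
    return px.simulate_tree(33, seed=11)


@pytest.fixture(scope="session")
def cov33(tree33):
    return px.vcv(tree33)


@pytest.fixture(scope="session")
def traits33(tree33):
    cfg = px.SimulationConfig(seed=11)
    traits, _ = px.simulate_traits(tree33, cfg, seed=np.random.default_rng(21))
    return traits


@pytest.fixture()
def small_matrix():
    """3 species x 2 replicates, 4 genes, hand-checkable FPKM values."""
    data = {
        "a_r1": [10.0, 4.0, 8.0, 0.0],
        "a_r2": [10.0, 4.0, 8.0, 0.0],
        "b_r1": [20.0, 4.0, 6.0, 5.0],
        "b_r2": [20.0, 4.0, 6.0, 5.0],
        "c_r1": [40.0, 4.0, 5.0, 5.0],
        "c_r2": [40.0, 4.0, 5.0, 5.0],
    }
    m = pd.DataFrame(data, index=["g1", "g2", "g3", "g4"])
    sheet = px.SampleSheet(pd.DataFrame({
        "sample_id": list(data),
        "species": ["a", "a", "b", "b", "c", "c"],
        "organ": "liver",
        "replicate": [1, 2] * 3,
    }))
    return m, sheet
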