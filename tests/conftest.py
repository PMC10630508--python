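import numpy as np
import pytest

from epsc_typer import synthio


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_arm_cell():
    """Default two-arm cell spec with a fixed seed."""
    return synthio.CellSpec(cell_id="cellA", s_fraction=0.6, seed=42)


@pytest.fixture()
def mixed_pair():
    return synthio.PairSpec(pair_id="pairA", pair_type="Mixed", freq=20.0,
                            n_sweeps=15, seed=7)
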