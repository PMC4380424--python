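import numpy as np
import pytest

from metastab import chem_graph


@pytest.fixture
def benzene():
    return chem_graph.parse_smiles("c1ccccc1")


@pytest.fixture
def butane():
    return chem_graph.parse_smiles("CCCC")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def first_order_series(compound_id, t_half, times=(0, 5, 10, 15, 30),
                       replicate=1, r0=1.0, is_area=1e5):
    """Noiseless first-order depletion series with unit-area IS."""
    from metastab.kinetics import DepletionSeries

    times = np.asarray(times, dtype=float)
    ratio = r0 * np.exp2(-times / t_half)
    return DepletionSeries(
        compound_id, replicate, times, is_area * ratio, np.full(len(times), is_area)
    )
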