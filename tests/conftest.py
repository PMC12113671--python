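import numpy as np
import pytest

import seedfrost as sf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_grid():
    return sf.WavelengthGrid(np.array([450.0, 700.0, 979.0]))


@pytest.fixture
def small_table():
    """48-seed, 40-band synthetic table with planted ground truth."""
    cfg = sf.default_config(
        "endosperm", seed=7, class_sizes=(20, 16, 12), n_bands=40
    )
    table, truth = sf.gen_spectra(cfg)
    return table, truth


def make_cube(values, centers=None):
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = np.linspace(450, 979, values.shape[2])
    return sf.HyperCube(values, sf.WavelengthGrid(np.asarray(centers, float)))
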