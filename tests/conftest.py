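import numpy as np
import pytest

from finsize.fixtures import (
    born_ion,
    ideal_helix_octapeptide,
    random_neutral_cloud,
    rocksalt_cell,
)


@pytest.fixture(scope="session")
def helix():
    """Ideal helical alanine octapeptide with end-to-end anchor indices."""
    system, n_index, c_index = ideal_helix_octapeptide()
    return system, n_index, c_index


@pytest.fixture(scope="session")
def rocksalt():
    return rocksalt_cell(a=0.564, n_cells=1)


@pytest.fixture()
def neutral_cloud():
    return random_neutral_cloud(n_pairs=4, box_edge=2.0, min_sep=0.3, seed=1)


@pytest.fixture()
def periodic_born():
    return born_ion(q=1.0, radius=0.2, box_edge=3.0)
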