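import numpy as np
import pytest

from bselsdm.geodata import RasterGrid, StudyArea


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """10x10 grid of 5-km cells with two smooth covariate bands."""
    n = 10
    g = RasterGrid(origin_x=0.0, origin_y=n * 5.0, cell_size=5.0, n_rows=n, n_cols=n)
    cx, cy = g.cell_centers()
    g.add_band("bio1", ((cx - cx.mean()) / cx.std()).astype(float))
    g.add_band("bio2", ((cy - cy.mean()) / cy.std()).astype(float))
    return g


@pytest.fixture
def square_area():
    return StudyArea.from_rectangle(0.0, 0.0, 50.0, 50.0)


@pytest.fixture(scope="session")
def tiny_scenario():
    """A small end-to-end scenario shared by the slower model tests."""
    from bselsdm.synthetic import make_scenario

    return make_scenario(seed=42, n_rows=30, n_cols=30, n_presences=120, M=5)
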