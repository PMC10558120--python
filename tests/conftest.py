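import numpy as np
import pytest

from standweave import synthetic
from standweave.pointcloud import PointCloud


@pytest.fixture(scope="session")
def pool():
    return synthetic.default_species_pool()


@pytest.fixture(scope="session")
def design(pool):
    return synthetic.generate_design(pool, seed=11)


@pytest.fixture(scope="session")
def mono_plot(design):
    return next(p for p in design.plots if p.richness == 1)


@pytest.fixture(scope="session")
def four_species_plot(design):
    return next(p for p in design.plots if p.richness == 4)


@pytest.fixture(scope="session")
def census(mono_plot, pool):
    trees = synthetic.layout_plot(mono_plot, seed=21, pool=pool)
    return synthetic.simulate_growth(trees, pool, seed=22)


@pytest.fixture(scope="session")
def cloud(mono_plot, census, pool):
    return synthetic.simulate_scan(mono_plot, census, pool, seed=23)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform([0, 0, 0], [11, 11, 8], size=(2000, 3)))
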