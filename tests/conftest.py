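import numpy as np
import pytest

from omicsview import fixtures
from omicsview.data_io import ExpressionDataset


@pytest.fixture(scope="session")
def spec():
    return fixtures.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def tables(spec):
    return fixtures.generate_tables(spec)


@pytest.fixture(scope="session")
def fixture_dir(spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fx")
    fixtures.generate(spec, out)
    return out


@pytest.fixture(scope="session")
def go_graph(tables):
    return fixtures.as_go_graph(tables)


@pytest.fixture
def small_ds():
    # 4 entities x 3 samples with one missing cell and a zero
    vals = np.array([
        [5.0, 5.0, 1.0],
        [6.0, 2.0, 0.0],
        [np.nan, 4.0, 8.0],
        [50.0, 50.0, 10.0],
    ])
    return ExpressionDataset(["g1", "g2", "g3", "g4"], ["A", "B", "C"], vals)
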