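import numpy as np
import pytest

from otusynth.fixtures import FixtureConfig, make_fixture
from otusynth.io import OtuTable, SampleMeta


@pytest.fixture(scope="session")
def small_fixture():
    """Paper-shaped sample layout, 50 features, planted effect 4."""
    return make_fixture(FixtureConfig(seed=11, n_features=50))


@pytest.fixture(scope="session")
def crc_biopsy_group(small_fixture):
    """One real (condition, specimen) group to fit synthesizers on."""
    from otusynth.io import partition

    table, meta, _ = small_fixture
    g_table, g_meta = partition(table, meta, by=("condition", "specimen"))[("CRC", "biopsy")]
    return g_table, g_meta


@pytest.fixture
def toy_table():
    return OtuTable(
        ["s1", "s2", "s3"],
        ["Family;GenusA", "Family;GenusB"],
        np.array([[0.0, 5.0], [2.0, 0.0], [1.0, 1.0]]),
    )


@pytest.fixture
def toy_meta():
    return [
        SampleMeta("s1", "p1", "AP", "stool"),
        SampleMeta("s2", "p1", "CRC", "biopsy"),
        SampleMeta("s3", "p2", "CRC", "saliva"),
    ]
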