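import numpy as np
import pytest

from cemusa.io import SpatialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    """Corner coordinates of the unit square, row-major order."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


@pytest.fixture
def small_dataset():
    """Six spots, two clean spatial domains, identity prediction."""
    coords = np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [10.0, 0.0], [11.0, 0.0], [10.0, 1.0]]
    )
    labels = np.array([1, 1, 1, 2, 2, 2])
    return SpatialDataset.from_arrays(coords, labels, labels)


@pytest.fixture
def spot_table(tmp_path):
    """Write a 4-row TSV spot table and return its path."""
    path = tmp_path / "spots.tsv"
    path.write_text(
        "spot_id\tx\ty\ttruth\tpred\n"
        "s1\t0\t0\tA\tu\n"
        "s2\t1\t0\tA\tu\n"
        "s3\t0\t1\tB\tv\n"
        "s4\t1\t1\tB\tv\n"
    )
    return path
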