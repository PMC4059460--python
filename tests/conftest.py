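import numpy as np
import pytest

from derseg.coverage import CoverageMatrix, DesignMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_design():
    """Balanced 2+2 design without confounders or depth normalization."""
    return DesignMatrix(groups=["a", "a", "b", "b"])


def make_cov(counts, chrom="chrT", start=0, sample_ids=None):
    counts = np.asarray(counts)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(counts.shape[1])]
    return CoverageMatrix(
        chrom=chrom,
        positions=np.arange(start, start + counts.shape[0]),
        counts=counts,
        sample_ids=sample_ids,
    )


@pytest.fixture
def small_cov():
    """5 bases x 4 samples with one clearly expressed stretch."""
    counts = np.array(
        [
            [0, 0, 0, 0],
            [10, 12, 9, 11],
            [20, 22, 19, 21],
            [18, 20, 17, 19],
            [0, 1, 0, 0],
        ]
    )
    return make_cov(counts)
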