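import numpy as np
import pytest

from flexiverse import FixedInterval, RegionSet, RegionSetCollection


def random_collection(rng, n_sets=3, genome_len=200, max_regions=6, chroms=("chr1",)):
    """A small random collection for oracle comparisons."""
    sets = []
    for i in range(n_sets):
        intervals = []
        for chrom in chroms:
            for _ in range(rng.integers(0, max_regions + 1)):
                a = int(rng.integers(0, genome_len - 1))
                b = int(rng.integers(a + 1, min(genome_len, a + 40) + 1))
                intervals.append(FixedInterval(chrom, a, b))
        sets.append(RegionSet(f"set_{i}", intervals))
    return RegionSetCollection(sets)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_set_collection():
    """The canonical worked example: [0,10) and [5,15) on a 20 bp genome."""
    return RegionSetCollection(
        [
            RegionSet("a", [FixedInterval("chr1", 0, 10)]),
            RegionSet("b", [FixedInterval("chr1", 5, 15)]),
        ]
    )


@pytest.fixture
def chr1_20():
    return {"chr1": 20}
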