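import numpy as np
import pytest

from chicbench import BaitMap, Fragment, FragmentMap


@pytest.fixture
def six_fragment_map() -> FragmentMap:
    """Two chromosomes tiled by six fragments."""
    return FragmentMap(
        [
            Fragment("chr1", 1, 999, 1),
            Fragment("chr1", 1000, 2000, 2),
            Fragment("chr1", 2001, 2099, 3),
            Fragment("chr1", 2100, 3000, 4),
            Fragment("chr1", 3001, 6000, 5),
            Fragment("chr2", 1, 5000, 6),
        ]
    )


@pytest.fixture
def bait_map(six_fragment_map) -> BaitMap:
    return BaitMap.from_ids([2, 5], six_fragment_map)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
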