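import numpy as np
import pytest

from clrde.io import CountTable, DesignTwoGroup


@pytest.fixture
def small_counts() -> CountTable:
    """200 genes x 4 samples of moderate random counts."""
    rng = np.random.default_rng(42)
    d = 200
    return CountTable(
        [f"g{i:03d}" for i in range(d)],
        ["s1", "s2", "s3", "s4"],
        rng.integers(0, 500, size=(d, 4)),
    )


@pytest.fixture
def two_group_design() -> DesignTwoGroup:
    return DesignTwoGroup({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
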