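import numpy as np
import pytest

from screenmle.data import CountMatrix, DesignMatrix, SgRNALibrary
from screenmle.simulate import default_design


@pytest.fixture
def tiny_library() -> SgRNALibrary:
    return SgRNALibrary(
        sgrna_ids=("g1_a", "g1_b", "g2_a"),
        gene_ids=("g1", "g1", "g2"),
        spacers=("ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT", "GATTACAGATTACAGATTAC"),
    )


@pytest.fixture
def tiny_counts(tiny_library) -> CountMatrix:
    return CountMatrix(
        tiny_library.sgrna_ids,
        ("day0", "treated"),
        np.array([[100, 50], [80, 40], [120, 240]]),
    )


@pytest.fixture
def two_sample_design() -> DesignMatrix:
    return DesignMatrix(("day0", "treated"), ("treatment",), np.array([[0], [1]]))


@pytest.fixture
def screen_design() -> DesignMatrix:
    """1 day-0 baseline sample + 2 conditions x 2 replicates (J=5, R=2)."""
    return default_design(n_condition_samples=2, n_replicates=2, baseline_samples=1)
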