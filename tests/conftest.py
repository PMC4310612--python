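import numpy as np
import pytest

from tissueqtl.links import InsertSizeDistribution
from tissueqtl.types import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def three_exon_gene():
    """150bp exons separated by 500bp introns, + strand."""
    return GeneModel(
        "gA", "chr1", "+",
        [(1000, 1150), (1650, 1800), (2300, 2450)],
    )


@pytest.fixture
def insert_dist():
    return InsertSizeDistribution.from_dict({180: 0.25, 200: 0.50, 220: 0.25})
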