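import numpy as np
import pytest

from shmstop.synthetic import generate_template
from shmstop.template import (
    VGeneTemplate,
    find_hotspot_motifs,
    partition_regions,
)


@pytest.fixture(scope="session")
def toy_template():
    """9-nt toy with known codon risks: CAA (1), TAT (2), GGG (0)."""
    return VGeneTemplate("toy", "CAATATGGG")


@pytest.fixture(scope="session")
def synthetic_template():
    """A realistic 393-nt synthetic template with CDR annotations."""
    return generate_template(rng=3)


@pytest.fixture(scope="session")
def synthetic_partition(synthetic_template):
    motifs = find_hotspot_motifs(synthetic_template)
    return partition_regions(synthetic_template, motifs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
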