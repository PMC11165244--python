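import numpy as np
import pytest

from splicetarget.core import TranscriptModel
from splicetarget.fixtures import make_toy_reference


@pytest.fixture(scope="session")
def tx1() -> TranscriptModel:
    """Canonical plus-strand fixture: three exons with a CDS."""
    return TranscriptModel(
        "TX1", "GENE1", "chrT", "+",
        exons=((101, 200), (301, 400), (501, 600)),
        cds=((132, 200), (301, 400), (501, 562)),
    )


@pytest.fixture(scope="session")
def tx1_minus() -> TranscriptModel:
    """Minus-strand twin of tx1 (same coordinates, opposite orientation)."""
    return TranscriptModel(
        "TX1m", "GENE1", "chrT", "-",
        exons=((101, 200), (301, 400), (501, 600)),
    )


@pytest.fixture(scope="session")
def reference():
    return make_toy_reference(seed=0)


@pytest.fixture(scope="session")
def genome(reference):
    return reference.genome


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
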