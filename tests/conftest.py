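import numpy as np
import pytest

from peroxikit.sequence import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def random_record(rng):
    return ProteinRecord("rand", random_protein(rng, 200))
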