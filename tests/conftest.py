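import numpy as np
import pytest

from genefam.promoters import CisElementCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(20160718)


@pytest.fixture(scope="session")
def catalog():
    return CisElementCatalog.default()


def random_protein(rng, n: int) -> str:
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(residues[rng.integers(0, 20, n)])
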