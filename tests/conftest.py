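import numpy as np
import pytest

from editaudit.homology import GuideSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20230918)


@pytest.fixture
def guide():
    # SpRY-style degenerate PAM, 20-nt protospacer, 12-nt seed
    return GuideSpec("GTCACGTTAGCATCTGAACT", "NRN", seed_length=12)


@pytest.fixture
def ngg_guide():
    return GuideSpec("ACGTACGTACGTACGTACGT", "NGG", seed_length=12)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
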