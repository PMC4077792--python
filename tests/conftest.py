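import random

import numpy as np
import pytest

from itsfold.fold import load_default_model


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng_or_seed, n: int, alphabet: str = "ACGU") -> str:
    if isinstance(rng_or_seed, int):
        rng_or_seed = random.Random(rng_or_seed)
    return "".join(rng_or_seed.choice(alphabet) for _ in range(n))


@pytest.fixture()
def pyrandom():
    return random.Random(987)
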