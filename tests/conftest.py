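import numpy as np
import pytest

from clonetrace import AnchorConfig, DEFAULT_ANCHOR


@pytest.fixture(scope="session")
def anchor_config() -> AnchorConfig:
    return AnchorConfig()


@pytest.fixture(scope="session")
def anchor() -> str:
    return DEFAULT_ANCHOR


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
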