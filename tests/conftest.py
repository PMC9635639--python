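import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return letters[rng.integers(0, len(letters), size=length)].tobytes().decode()


@pytest.fixture()
def make_dna(rng):
    def _make(length: int, alphabet: str = "ACGT") -> str:
        return random_dna(rng, length, alphabet)

    return _make
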