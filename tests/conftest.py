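import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def random_dna(rng):
    def make(length: int, with_n: bool = False) -> str:
        alphabet = "ACGTN" if with_n else "ACGT"
        probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
        return "".join(rng.choice(list(alphabet), size=length, p=probs))

    return make
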