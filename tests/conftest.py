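import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from maskfer import synthfaces


@pytest.fixture(scope="session")
def default_face():
    """One deterministic default-profile synthetic upper face."""
    return synthfaces.generate_upper_face(synthfaces.SyntheticFaceSpec(rng_seed=3))


@pytest.fixture(scope="session")
def face_batch():
    """Fifty seeded default fixtures for recovery-rate statistics."""
    return [
        synthfaces.generate_upper_face(synthfaces.SyntheticFaceSpec(rng_seed=s))
        for s in range(50)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
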