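import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bayesmig import synthetic


@pytest.fixture(scope="session")
def small_world():
    """Synthetic world small enough for fast unit tests."""
    return synthetic.generate(
        synthetic.SyntheticSpec(C=5, T=8, seed=42, horizon_periods=6)
    )


@pytest.fixture(scope="session")
def recovery_world():
    """The C=40, T=12 ground-truth world used by recovery/calibration tests."""
    return synthetic.generate(
        synthetic.SyntheticSpec(C=40, T=12, seed=2015, horizon_periods=6)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
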