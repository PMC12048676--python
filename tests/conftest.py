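import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
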