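import numpy as np
import pytest

from m5u.windows import RnaWindow, WindowSet, generate_synthetic


def random_window_seq(rng: np.random.Generator, L: int = 41) -> str:
    """A random ACGU string of odd length with a U forced at the center."""
    chars = list(rng.choice(list("ACGU"), size=L))
    chars[L // 2] = "U"
    return "".join(chars)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_windows(rng):
    """50 random 41-nt uridine-centered windows."""
    return [
        RnaWindow(id=f"w{i}", seq=random_window_seq(rng)) for i in range(50)
    ]


@pytest.fixture
def motif_dataset():
    """Balanced synthetic set with the UUC consensus planted in positives."""
    return generate_synthetic(
        n_pos=100, n_neg=100, motif="UUC", motif_offset=0, motif_prob=1.0, seed=7
    )
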