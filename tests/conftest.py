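import numpy as np
import pytest

from hypnoval.hypnogram import Hypnogram
from hypnoval.stages import HARMONIZED4, PSG5


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def psg5_hypnogram():
    return Hypnogram(
        "S000", "reviewer1", 0.0, 30.0,
        ("WAKE", "N1", "N2", "N2", "N3", "REM", "WAKE"), PSG5,
    )


def random_hypnogram(rng, n, vocabulary=HARMONIZED4, epoch_s=30.0, onset_s=0.0):
    stages = tuple(rng.choice(vocabulary.stages, size=n))
    return Hypnogram("R", "truth", onset_s, epoch_s, stages, vocabulary)
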