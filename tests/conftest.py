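import numpy as np
import pytest

from proinflam.model import ModelConfig, train
from proinflam.motifs import BETTS_RUSSELL
from proinflam.sequence_io import ALPHABET, PeptideRecord


def make_records(sequences, label=None, prefix="r"):
    return [
        PeptideRecord(f"{prefix}{i}", s, label=label)
        for i, s in enumerate(sequences)
    ]


def random_peptides(rng, n, min_len=4, max_len=30):
    out = []
    for _ in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append("".join(ALPHABET[i] for i in rng.integers(0, 20, size=L)))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def separable_model():
    """AAC model on trivially separable data (A-rich vs C-rich peptides)."""
    rng = np.random.default_rng(7)
    pos = make_records(
        ["".join("A" if rng.random() < 0.9 else "G" for _ in range(12)) for _ in range(12)],
        label="positive", prefix="p",
    )
    neg = make_records(
        ["".join("C" if rng.random() < 0.9 else "G" for _ in range(12)) for _ in range(12)],
        label="negative", prefix="n",
    )
    config = ModelConfig("AAC", gamma=0.001, cost=10, cost_factor=1, threshold=0.0)
    return train(pos + neg, config, seed=0), pos, neg


@pytest.fixture(scope="session")
def betts():
    return BETTS_RUSSELL
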