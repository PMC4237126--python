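import numpy as np
import pytest

from phylogrid import seqio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_alignment():
    return seqio.Alignment.from_sequences(
        {"s1": "ACGTA", "s2": "AC--A", "s3": "ACGTA", "s4": "ACGTT"}
    )


@pytest.fixture
def tiny_samples():
    return seqio.SampleTable.from_records(
        [
            ("s1", "spX", 0.5, 9.25),
            ("s2", "spX", 0.6, 9.30),
            ("s3", "spX", 2.5, 12.0),
            ("s4", "spX", 2.6, 12.1),
        ]
    )


def random_alignment(rng, n=20, length=50, gap_prob=0.0):
    """Random nucleotide alignment (no N), optional single-column gaps."""
    bases = np.array(list("ACGT"))
    mat = rng.choice(bases, size=(n, length))
    if gap_prob:
        mask = rng.random(size=(n, length)) < gap_prob
        mat = np.where(mask, "-", mat)
    return seqio.Alignment.from_sequences(
        {f"s{i}": "".join(row) for i, row in enumerate(mat)}
    )
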