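import numpy as np
import pytest

from foldprep.fixtures import make_msa
from foldprep.msa import AlignedSequence, Msa


@pytest.fixture
def small_msa() -> Msa:
    """60-column MSA with 50 rows spread over the five identity buckets."""
    return make_msa(50, 60, [0.1, 0.3, 0.5, 0.7, 0.9], seed=7)


@pytest.fixture
def tiny_msa() -> Msa:
    return Msa([
        AlignedSequence("q", "ACDEFG"),
        AlignedSequence("h1", "ACDEFG"),
        AlignedSequence("h2", "AC-E-G"),
        AlignedSequence("h3", "ACDEfgFG"),  # two-residue insertion after E
    ])


def brute_force_max_identity(rows):
    """Oracle: all-pairs maximum identity by direct counting."""
    from foldprep.msa import pairwise_identity

    best = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            best = max(best, pairwise_identity(rows[i], rows[j]))
    return best
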