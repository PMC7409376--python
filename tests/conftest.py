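import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from goatalign import AlignmentParams, FamilySimilarityMatrix, GenomeProfile


@pytest.fixture
def identity_matrix():
    """Identity-like substitution matrix over single-letter labels."""
    return FamilySimilarityMatrix.identity(list("ABCDEFGHXY"))


@pytest.fixture
def half_gap_params():
    return AlignmentParams(gap_penalty=0.5)


@pytest.fixture
def profile():
    """Factory: profile from a label string, e.g. profile('ABCD')."""

    def make(labels, genome_id="g", circular=True, strands=None):
        return GenomeProfile(
            genome_id=genome_id,
            families=tuple(labels),
            strands=tuple(strands) if strands else None,
            circular=circular,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_profile_pair(rng, max_len=8, alphabet="ABCDEFGH"):
    """Two random circular profiles over a small shared alphabet."""
    la = int(rng.integers(2, max_len + 1))
    lb = int(rng.integers(2, max_len + 1))
    fa = [alphabet[i] for i in rng.integers(0, len(alphabet), size=la)]
    fb = [alphabet[i] for i in rng.integers(0, len(alphabet), size=lb)]
    return (
        GenomeProfile("a", tuple(fa), None, True),
        GenomeProfile("b", tuple(fb), None, True),
    )
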