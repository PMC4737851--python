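import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from kryptic.seqcore import Sequence
from kryptic.synthetic_data import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def default_community():
    """The default five-genome community (200 kbp each, seed 42)."""
    return generate_community(CommunitySpec())


@pytest.fixture(scope="session")
def small_community():
    """A lighter three-genome community for quicker stage tests."""
    spec = CommunitySpec(n_genomes=3, genome_length=80_000,
                         contig_length_range=(5_000, 20_000), rng_seed=7)
    return generate_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def make_seq():
    def _make(residues, sid="s"):
        return Sequence(sid, residues)

    return _make
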