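import numpy as np
import pytest

from metacon.io import ContigRecord, ContigSet, CoverageMatrix
from metacon.synthetic import CommunitySpec, generate_community

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int,
                    probs=(0.25, 0.25, 0.25, 0.25), n_rate: float = 0.0) -> str:
    draws = rng.choice(4, size=length, p=list(probs))
    seq = _BASES[draws].tobytes().decode()
    if n_rate > 0:
        chars = list(seq)
        for i in np.flatnonzero(rng.random(length) < n_rate):
            chars[i] = "N"
        seq = "".join(chars)
    return seq


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_contigs():
    return ContigSet(
        [
            ContigRecord("c1", "ACGTACGTAC"),
            ContigRecord("c2", "GGGGCCCCGG"),
            ContigRecord("c3", "ATATATATAT"),
        ]
    )


@pytest.fixture
def tiny_coverage(tiny_contigs):
    return CoverageMatrix(
        values=np.array([[2.0, 0.0], [1.0, 3.0], [4.0, 4.0]]),
        sample_ids=["s1", "s2"],
        contig_ids=tiny_contigs.ids,
    )


@pytest.fixture(scope="session")
def small_community():
    """A small, clearly separated 3-species community for fast end-to-end
    tests."""
    spec = CommunitySpec(G=3, samples=4, contigs_per_species=20,
                         short_fraction=0.25, seed=7)
    return generate_community(spec)
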