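import numpy as np
import pytest

from oligofish.genome_model import GenomeIndex
from oligofish.synthetic_data import SimGenomeParams, simulate_genome


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=n, p=[0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]
                      ).tobytes().decode()


@pytest.fixture(scope="session")
def small_genome() -> GenomeIndex:
    """One random 10 kb chromosome, indexed at k=18."""
    rng = np.random.default_rng(42)
    return GenomeIndex({"chrS": random_seq(rng, 10_000, gc=0.45)}, k=18)


@pytest.fixture(scope="session")
def two_chrom_genome() -> GenomeIndex:
    """Two random 100 kb chromosomes (spans one 500 kb segment each)."""
    seqs, _ = simulate_genome(
        SimGenomeParams(n_chrom=2, chrom_length=100_000, gc=0.45, seed=7))
    return GenomeIndex(seqs, k=18)
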