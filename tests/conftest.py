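import numpy as np
import pytest

from popcnv.core_io import CnvCall, GenomeDef
from popcnv.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeDef(
        lengths={"chr1": 1_000_000, "chr2": 800_000, "chrX": 600_000}
    )


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel shared by read-only tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for tests that re-simulate across seeds."""
    return SimConfig(
        seed=0,
        n_chromosomes=2,
        chrom_length=6_000_000,
        n_samples={
            "classical": 6,
            "wild_derived": 4,
            "wild_caught_dom": 4,
            "wild_caught_mus": 4,
        },
        n_cnvrs=6,
        n_unique_per_sample={
            "classical": 1,
            "wild_derived": 2,
            "wild_caught_dom": 2,
            "wild_caught_mus": 2,
        },
        max_anchor_len=150_000,
    )


def random_calls(rng, n, genome, max_len=10_000, samples=("s1", "s2", "s3")):
    """Random valid calls over a genome, for oracle-equivalence tests."""
    chroms = sorted(genome.lengths)
    calls = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(1, genome.lengths[chrom] - length + 2))
        state = int(rng.choice([0, 1, 3, 4]))
        calls.append(
            CnvCall(
                sample_id=str(rng.choice(list(samples))),
                chrom=chrom,
                start=start,
                end=start + length - 1,
                copy_state=state,
                n_markers=int(rng.integers(3, 50)),
            )
        )
    return calls
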