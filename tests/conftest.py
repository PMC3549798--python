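import numpy as np
import pytest

import fasthash as fh


@pytest.fixture(scope="session")
def tiny_genome():
    return fh.ReferenceGenome([("chr1", "ACGTACGT")])


@pytest.fixture(scope="session")
def tiny_index(tiny_genome):
    return fh.build_index(tiny_genome, fh.IndexParams(k=4))


@pytest.fixture(scope="session")
def sim_bundle():
    """A mid-size random genome with indexed reads + truth, shared across tests."""
    cfg = fh.SimConfig(
        genome_length=20_000, n_reads=120, read_length=72, max_edits=3, rng_seed=2024
    )
    genome = fh.make_genome(cfg)
    index = fh.build_index(genome, fh.IndexParams(k=12))
    reads, truths = fh.simulate_reads(genome, cfg)
    return cfg, genome, index, reads, truths


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
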