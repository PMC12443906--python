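import pytest

from syntelog import (
    GeneOrder,
    HitRecord,
    InitialAssignment,
    Locus,
    SimParams,
    simulate,
)


def make_chromosome(blocks, scores, chrom="chr1"):
    """One chromosome of consecutive loci g0, g1, ... with given initial
    block labels (None = no hit) and bitscores."""
    loci = [
        Locus(f"g{i}", chrom, i * 100, i * 100 + 50) for i in range(len(blocks))
    ]
    initials = [
        InitialAssignment(f"g{i}", f"r{i}", scores[i], blocks[i])
        for i in range(len(blocks))
        if blocks[i] is not None
    ]
    return GeneOrder(loci), initials


def hits(*triples):
    return [HitRecord(q, s, b) for q, s, b in triples]


@pytest.fixture(scope="session")
def small_trap_dataset():
    """A small seeded instance with planted traps, shared across tests."""
    return simulate(
        SimParams(seed=20260930, n_blocks=6, genes_per_block=10, p_trap=0.2,
                  n_accessions=3)
    )


@pytest.fixture(scope="session")
def small_easy_dataset():
    """Small instance in the easy regime: no traps, no noise, no paralogs."""
    return simulate(
        SimParams(seed=20260930, n_blocks=6, genes_per_block=10, p_trap=0.0,
                  paralog_fraction=0.0, noise_rate=0.0, dropout=0.0,
                  n_accessions=3)
    )
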