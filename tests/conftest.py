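import numpy as np
import pytest

from paircomp import (
    AncestorSpec,
    DivergenceSpec,
    diverge_pair,
    generate_ancestor,
)


def mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Simple uniform mutation helper for toy alignment fixtures."""
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            out[i] = bases[(bases.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_ancestor():
    return generate_ancestor(AncestorSpec(genome_length=30_000, seed=11))


@pytest.fixture(scope="session")
def small_pair(small_ancestor):
    """30 kb pair at 10% divergence with 10% gene loss per lineage."""
    a, b, truth = diverge_pair(
        small_ancestor,
        DivergenceSpec(site_divergence=0.10, gene_loss_fraction=0.10, seed=12),
    )
    return a, b, truth


@pytest.fixture(scope="session")
def close_pair(small_ancestor):
    """30 kb pair at 5% divergence, no gene loss (orthology fully recoverable)."""
    a, b, truth = diverge_pair(
        small_ancestor,
        DivergenceSpec(site_divergence=0.05, gene_loss_fraction=0.0, seed=13),
    )
    return a, b, truth
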