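import pytest

from metachrom.synthetic_data import (
    FixtureSpec,
    gen_counts,
    gen_genome,
    gen_links_and_expression,
)


@pytest.fixture(scope="session")
def spec_small() -> FixtureSpec:
    """A reduced fixture spec for fast module tests."""
    return FixtureSpec(
        seed=7,
        chrom_sizes={"chr1": 2_000_000, "chr2": 2_000_000},
        n_peaks=300,
        n_links=80,
        n_patients=120,
    )


@pytest.fixture(scope="session")
def genome_small(spec_small):
    return gen_genome(spec_small)


@pytest.fixture(scope="session")
def counts_small(spec_small, genome_small):
    return gen_counts(spec_small, genome_small["peaks"])


@pytest.fixture(scope="session")
def loops_small(spec_small, genome_small, counts_small):
    _, truth = counts_small
    return gen_links_and_expression(spec_small, genome_small, truth)
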