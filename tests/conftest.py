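import pytest

from tebench import (
    FixtureSpec,
    SimConfig,
    TreeConfig,
    generate_dna_transposon_tree,
    make_rate_matrix,
    make_seed_sequence,
    simulate,
)


@pytest.fixture(scope="session")
def rate_matrix():
    return make_rate_matrix()


@pytest.fixture(scope="session")
def seed_300():
    return make_seed_sequence(FixtureSpec(seed_length=300, cpg_enrichment=3.0, rng_seed=2))


@pytest.fixture(scope="session")
def seed_1200():
    return make_seed_sequence(FixtureSpec(seed_length=1200, cpg_enrichment=3.0, rng_seed=42))


@pytest.fixture(scope="session")
def small_family(seed_300, rate_matrix):
    """A 10-copy simulated family at ~5% divergence with indels."""
    tree = generate_dna_transposon_tree(TreeConfig(n_leaves=10, rng_seed=1))
    return simulate(tree, seed_300, rate_matrix, SimConfig(gput=500, rng_seed=3))
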