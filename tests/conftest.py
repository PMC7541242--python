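import pytest

from het5c import synthetic


@pytest.fixture(scope="session")
def genome():
    return synthetic.toy_genome(seed=0)


@pytest.fixture(scope="session")
def primers(genome):
    return synthetic.generate_primer_set(genome, 10_000)


@pytest.fixture(scope="session")
def model(genome):
    return synthetic.toy_model(genome, read_depth=200_000, n_replicates=3)


@pytest.fixture(scope="session")
def tables(primers, model):
    return synthetic.simulate_contact_counts(primers, model, seed=0)


@pytest.fixture(scope="session")
def small_table(genome):
    """A small single-replicate count table on a 300 kb genome."""
    g = synthetic.toy_genome(seed=3, length=300_000)
    m = synthetic.PlantedTADModel(
        tads=(("chrT", 0, 150_000, "active"), ("chrT", 150_000, 300_000, "inactive")),
        read_depth=5_000,
        n_replicates=1,
    )
    ps = synthetic.generate_primer_set(g, 10_000)
    return ps, synthetic.simulate_contact_counts(ps, m, seed=3)[0]
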