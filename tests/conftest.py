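import pytest

from tssarna import default_plants, detect_all, emit_reads, make_genome


@pytest.fixture(scope="session")
def genome():
    genes, seq = make_genome(n_genes=20, replicon_length=50_000, seed=1)
    return genes, seq


@pytest.fixture(scope="session")
def planted(genome):
    """20 planted TSSaRNAs above thresholds, zero noise, plus truth table."""
    genes, _ = genome
    plants = default_plants(genes, seed=2, n_primary=12, n_de=6)
    reads, truth = emit_reads(genes, plants, noise_rate=0.0, seed=3)
    return genes, plants, reads, truth


@pytest.fixture(scope="session")
def detected(planted):
    genes, _, reads, truth = planted
    return genes, truth, detect_all(genes, reads)
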