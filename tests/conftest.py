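import numpy as np
import pytest

from skincat import synthetic_data as sd


@pytest.fixture(scope="session")
def small_species_set():
    """Three unrelated species, compact genomes, 20 markers."""
    return sd.generate_species_set(
        n_species=3, genome_length=20_000, n_genes_per_genome=12,
        seed=11, n_markers=20)


@pytest.fixture(scope="session")
def genome(small_species_set):
    return small_species_set.genomes["sp1"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
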