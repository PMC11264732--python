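import pytest

from cashcandi import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.GeneratorConfig(
        seed=11,
        n_chrom=2,
        chrom_length=150_000,
        n_planted_regions=8,
        coverage=20,
        island_rate=6e-5,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sd.make_genome(small_config)


@pytest.fixture(scope="session")
def small_counts(small_genome):
    """Strand-collapsed count tables for a 5/5/5 tissue discovery cohort."""
    groups = ("tumor_tissue", "normal_tissue", "healthy_plasma")
    return {
        g: {
            p.sample_id: sd.emit_counts(p, small_genome)
            for p in sd.make_profiles(small_genome, g, 5)
        }
        for g in groups
    }
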