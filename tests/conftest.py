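import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    """Two-contig toy genome with a forward and a reverse gene.

    c1: AAAAAATGGGGCCC  -> + strand gene with ATG at genomic index 5.
    c2: reverse-strand gene whose mRNA begins ATG at genomic index 9 (end).
    """
    from tirscope.sequence_io import GeneAnnotation, GenomeRecord

    genomes = {
        "c1": GenomeRecord("c1", "AAAAAATGGGGCCC"),
        # revcomp of CATTTT... : gene on '-' covering [4, 10) reads ATGAAA
        "c2": GenomeRecord("c2", "GGGGTTTCATCCCC"),
    }
    genes = [
        GeneAnnotation("gplus", "c1", 5, 11, "+"),
        GeneAnnotation("gminus", "c2", 4, 10, "-"),
    ]
    return genomes, genes


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully featured synthetic dataset shared across tests."""
    from tirscope.simulate import SyntheticConfig, generate_counts, generate_genome

    config = SyntheticConfig(seed=42, n_genes=200, hairpin_fraction_low_ard=0.5)
    bundle = generate_genome(config)
    rna, ribo = generate_counts(config, bundle.ground_truth)
    return config, bundle, rna, ribo
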