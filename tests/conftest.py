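import pytest

from orfweaver import synthetic_data as synth


@pytest.fixture(scope="session")
def truth6():
    """Six multi-exon genes on a toy genome (fixed seed)."""
    return synth.simulate_genome(n_genes=6, seed=11)


@pytest.fixture(scope="session")
def frag_between(truth6):
    """Fragmentation between genes only: every gene whole on one contig."""
    return synth.fragment_assembly(truth6, "between_genes", seed=12)


@pytest.fixture(scope="session")
def frag_within(truth6):
    """Two genes split inside an intron: those genes span two contigs."""
    return synth.fragment_assembly(truth6, "within_genes", within_genes=2, seed=12)


@pytest.fixture(scope="session")
def transcripts6(truth6):
    """Two overlapping error-free components per gene, with protein hits."""
    return synth.simulate_transcripts(truth6, fragments_per_gene=2, seed=13)
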