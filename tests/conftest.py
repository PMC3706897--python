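import pytest

from cghcnv import genomes as g
from cghcnv.design import design_probes


@pytest.fixture(scope="session")
def small_reference():
    """A 6 x 30 kb reference genome used across the design/calling tests."""
    cfg = g.GenomeConfig(n_contigs=6, contig_length=30_000)
    return g.generate_reference(cfg, seed=1)


@pytest.fixture(scope="session")
def design_result(small_reference):
    return design_probes(small_reference)


@pytest.fixture(scope="session")
def mechanism_set():
    """Rejection-sampled 299-indel set with the reported class mixture."""
    return g.generate_mechanism_set(seed=17)
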