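import pytest

from txseg.fixtures import toy_gene_G
from txseg.library import (
    assign_segment_ids,
    attach_sequences,
    segment_gene,
)
from txseg.preprocessing import build_exonic_bins


@pytest.fixture(scope="session")
def toy():
    """The three-exon two-isoform worked example (gene, genome)."""
    return toy_gene_G(seed=0)


@pytest.fixture(scope="session")
def toy_bins(toy):
    gene, _ = toy
    return build_exonic_bins(gene)


@pytest.fixture(scope="session")
def toy_segments(toy):
    """Oracle-verified maximal segment library of the toy gene at L=100."""
    gene, genome = toy
    _, _, _, segs = segment_gene(gene, 100)
    return attach_sequences(assign_segment_ids(segs), genome)
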