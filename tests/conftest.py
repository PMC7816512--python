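import numpy as np
import pytest

from retronaut.annotation import Exon, Gene


def make_gene(gene_id="gA", chrom="chr1", strand="+", exon_bounds=((0, 100), (200, 300), (400, 500))):
    return Gene(
        gene_id,
        chrom,
        strand,
        tuple(Exon(chrom, s, e, strand) for s, e in exon_bounds),
    )


@pytest.fixture
def three_exon_gene():
    """Exons (0,100), (200,300), (400,500): introns (100,200) and (300,400)."""
    return make_gene()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
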