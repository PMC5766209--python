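import numpy as np
import pytest

from spliceorder.gene_models import GeneModel, GenomicInterval, build_gene_models


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_exon_plus():
    """'+'-strand transcript: exons [100,200) [300,400) [500,600)."""
    (m,) = build_gene_models(
        [("tx1", "g1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])]
    )
    return m


@pytest.fixture
def three_exon_minus():
    """Same exon coordinates on the '-' strand."""
    (m,) = build_gene_models(
        [("tx1m", "g1", "chr1", "-", [(100, 200), (300, 400), (500, 600)])]
    )
    return m


def make_model(tid, strand, spans, chrom="chr1", gene=None):
    (m,) = build_gene_models([(tid, gene or tid, chrom, strand, spans)])
    return m


@pytest.fixture
def six_exon_plus():
    """5-intron '+' transcript with 200-nt exons and varied introns."""
    spans = []
    pos = 0
    intron_lens = [500, 800, 1200, 600, 900]
    for i in range(6):
        spans.append((pos, pos + 200))
        pos += 200 + (intron_lens[i] if i < 5 else 0)
    return make_model("tx6", "+", spans)
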