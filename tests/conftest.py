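import pytest

from kovalid.gene_model import GenomicInterval, Transcript
from kovalid.synthetic_data import SimConfig, make_toy_locus

TOY_GFF3 = """##gff-version 3
chr1\ttest\tgene\t1\t500\t.\t{strand}\t.\tID=g1
chr1\ttest\tmRNA\t1\t500\t.\t{strand}\t.\tID=t1;Parent=g1
chr1\ttest\texon\t1\t100\t.\t{strand}\t.\tID=t1.e1;Parent=t1;gene_id=g1
chr1\ttest\texon\t201\t300\t.\t{strand}\t.\tID=t1.e2;Parent=t1;gene_id=g1
chr1\ttest\texon\t401\t500\t.\t{strand}\t.\tID=t1.e3;Parent=t1;gene_id=g1
chr1\ttest\tCDS\t1\t100\t.\t{strand}\t0\tID=t1.c1;Parent=t1;gene_id=g1
chr1\ttest\tCDS\t201\t300\t.\t{strand}\t0\tID=t1.c2;Parent=t1;gene_id=g1
chr1\ttest\tCDS\t401\t500\t.\t{strand}\t0\tID=t1.c3;Parent=t1;gene_id=g1
"""


@pytest.fixture
def toy_gff3(tmp_path):
    """3-exon transcript: exons 1-100, 201-300, 401-500 (1-based, + strand)."""
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3.format(strand="+"))
    return path


@pytest.fixture
def toy_gff3_minus(tmp_path):
    path = tmp_path / "toy_minus.gff3"
    path.write_text(TOY_GFF3.format(strand="-"))
    return path


def make_three_exon_transcript(strand="+"):
    """Plain 3-exon transcript (0-based: [0,100), [200,300), [400,500)),
    fully coding."""
    exons = [
        GenomicInterval("chr1", 0, 100, strand),
        GenomicInterval("chr1", 200, 300, strand),
        GenomicInterval("chr1", 400, 500, strand),
    ]
    cds = [GenomicInterval("chr1", e.start, e.end, strand) for e in exons]
    return Transcript("t1", "g1", strand, exons, cds)


@pytest.fixture
def three_exon_transcript():
    return make_three_exon_transcript()


@pytest.fixture(scope="session")
def default_locus(tmp_path_factory):
    """Shared toy locus from the default simulation configuration."""
    cfg = SimConfig(seed=7)
    locus = make_toy_locus(cfg, tmp_path_factory.mktemp("locus"))
    return cfg, locus
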