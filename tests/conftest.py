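import numpy as np
import pytest

from auxrescan.genome_io import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TOY_FASTA = """\
>c1
{c1}
>c2
{c2}
"""

TOY_GFF = """\
##gff-version 3
c1\ttest\tgene\t1501\t2400\t.\t+\t.\tID=geneA
c1\ttest\tmRNA\t1501\t2400\t.\t+\t.\tID=geneA.1;Parent=geneA
c1\ttest\texon\t1501\t2400\t.\t+\t.\tParent=geneA.1
c1\ttest\tCDS\t2001\t2400\t.\t+\t0\tParent=geneA.1
c1\ttest\tgene\t2801\t3600\t.\t-\t.\tID=geneB
c1\ttest\tmRNA\t2801\t3600\t.\t-\t.\tID=geneB.1;Parent=geneB
c1\ttest\texon\t2801\t3600\t.\t-\t.\tParent=geneB.1
c1\ttest\tCDS\t2801\t3500\t.\t-\t0\tParent=geneB.1
"""


@pytest.fixture
def toy_genome(rng):
    from auxrescan.synthetic_data import random_sequence

    return {
        "c1": random_sequence(5000, (0.25, 0.25, 0.25, 0.25), rng),
        "c2": random_sequence(3000, (0.25, 0.25, 0.25, 0.25), rng),
    }


@pytest.fixture
def toy_genome_files(tmp_path, toy_genome):
    fasta = tmp_path / "genome.fasta"
    fasta.write_text(TOY_FASTA.format(c1=toy_genome["c1"], c2=toy_genome["c2"]))
    gff = tmp_path / "genes.gff3"
    gff.write_text(TOY_GFF)
    return fasta, gff


def make_gene(gene_id="g1", chrom="c1", strand="+", cds_start=2001,
              span=(1800, 2600), exons=None):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_start=cds_start,
        gene_span=span,
        exon_spans=tuple(exons) if exons else (span,),
    )
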