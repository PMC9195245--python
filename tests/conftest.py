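import numpy as np
import pytest

from peachscan.variant_io import VariantRecord


def make_record(
    chrom="chr1",
    pos=100,
    genotypes=(0, 1, 2),
    depths=None,
    gqs=None,
    mq=60.0,
    ref="A",
    alt="T",
):
    n = len(genotypes)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=np.array(genotypes, dtype=np.int8),
        depths=np.array(depths if depths is not None else [30] * n, dtype=np.int32),
        gqs=np.array(gqs if gqs is not None else [99] * n, dtype=np.int32),
        mapping_quality=mq,
    )


@pytest.fixture
def record_factory():
    return make_record


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tT\t50\tPASS\tMQ=60\tGT:DP:GQ\t0/0:30:99\t0/1:25:80\t1/1:20:70
chr1\t200\t.\tC\tG\t50\tPASS\tMQ=60\tGT:DP:GQ\t0/1:30:99\t./.:.:.\t0/0:15:60
chr1\t300\t.\tG\tA\t50\tPASS\tMQ=60\tGT:DP:GQ\t1/1:40:99\t1/1:35:95\t0/1:28:88
"""

MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t0/1
chr1\t200\t.\tC\tG,T\t50\tPASS\t.\tGT\t0/1\t1/2
chr1\t300\t.\tG\tA\t50\tPASS\t.\tGT\t1/1\t0/0
"""

GFF3_TWO_GENES = """\
##gff-version 3
chr1\ttest\tgene\t1000\t3000\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t1000\t3000\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\ttest\tCDS\t1000\t1500\t.\t+\t0\tID=g1.c1;Parent=g1.t1
chr1\ttest\tCDS\t2000\t3000\t.\t+\t0\tID=g1.c2;Parent=g1.t1
chr2\ttest\tgene\t500\t900\t.\t-\t.\tID=g2
chr2\ttest\tmRNA\t500\t900\t.\t-\t.\tID=g2.t1;Parent=g2
chr2\ttest\tCDS\t500\t900\t.\t-\t0\tID=g2.c1;Parent=g2.t1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return str(p)


@pytest.fixture
def multiallelic_vcf(tmp_path):
    p = tmp_path / "multi.vcf"
    p.write_text(MULTIALLELIC_VCF)
    return str(p)


@pytest.fixture
def gff3_file(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF3_TWO_GENES)
    return str(p)
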