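import numpy as np
import pytest

from diffsel import SyntheticSpec, build_snp_table, pbsnj_scan
from diffsel.variant_io import PopulationPanel


@pytest.fixture(scope="session")
def default_dataset():
    """The reference planted-sweep fixture: 4 populations (38/36/20/22
    haploids), 2e5 SNPs over 100 blocks, 50 sweeps planted in pop1."""
    return build_snp_table(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def default_scan(default_dataset):
    return pbsnj_scan(default_dataset.snps)


@pytest.fixture
def toy_panel():
    return PopulationPanel(
        populations=("popA", "popB"),
        sample_to_population={"s1": "popA", "s2": "popA", "s3": "popB", "s4": "popB"},
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=100000>
##contig=<ID=X,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
1\t100\t.\tA\tG\t.\t.\tAA=A\tGT\t1/1\t0/1\t0/1\t0/0
1\t200\t.\tC\tT\t.\t.\tAA=C\tGT\t0/1\t./.\t0/0\t0/0
1\t300\t.\tG\tA,T\t.\t.\tAA=G\tGT\t0/1\t0/0\t0/0\t0/2
1\t400\t.\tA\tG\t.\t.\tAA=G\tGT\t1/1\t0/1\t0/0\t0/1
1\t500\t.\tT\tC\t.\t.\tAA=N\tGT\t0/1\t0/0\t0/1\t0/0
X\t600\t.\tA\tC\t.\t.\tAA=A\tGT\t0/1\t0/0\t0/0\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
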