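import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Fine-mapping genotype table for a rice F2 seedling mutant: 14 recombinant
# plants scored at six markers bracketing the causal locus on Chr12. Seven
# plants share a breakpoint left of the locus (heterozygous across the four
# InDel markers), two share one right of it (heterozygous at the two SSR
# markers), five recombined outside the window entirely.
ABS_GENOTYPE_TSV = """\
plant	InDel1	InDel2	InDel3	InDel4	RM27694	RM27697
#chrom	Chr12	Chr12	Chr12	Chr12	Chr12	Chr12
#pos	4070394	4187138	4400174	4403614	4814750	4920770
6	A	A	A	A	A	A
8	A	A	A	A	A	A
14	A	A	A	A	H	H
15	A	A	A	A	A	A
17	H	H	H	H	A	A
19	A	A	A	A	A	A
24	H	H	H	H	A	A
26	A	A	A	A	A	A
42	H	H	H	H	A	A
64	A	A	A	A	H	H
66	H	H	H	H	A	A
84	H	H	H	H	A	A
94	H	H	H	H	A	A
104	H	H	H	H	A	A
"""


@pytest.fixture
def abs_genotype_path(tmp_path):
    p = tmp_path / "abs_genotypes.tsv"
    p.write_text(ABS_GENOTYPE_TSV)
    return p


@pytest.fixture
def abs_matrix(abs_genotype_path):
    from sbmap import variant_io

    return variant_io.read_genotype_table(abs_genotype_path)


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=Chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	MUT	CTRL
Chr1	101	.	A	T	.	PASS	.	GT:AD	0/1:12,8	0/0:20,0
Chr1	205	.	G	GTTTTTT	.	PASS	.	GT:AD	0/1:15,14	1/1:0,22
Chr1	300	.	C	A,T	.	PASS	.	GT:AD	0/1:5,5,5	0/0:9,0,3
"""


@pytest.fixture
def toy_vcf_path(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture(scope="session")
def hom_fixture(tmp_path_factory):
    """A complete homozygous-design (F2) dataset on disk, 30-plant pool at 40x."""
    from sbmap import cross_sim
    from sbmap.recombinant_mapping import Mode

    outdir = tmp_path_factory.mktemp("hom_fixture")
    spec = cross_sim.PedigreeSpec(mode=Mode.HOM_F2, n_selected=30)
    return cross_sim.make_fixture(
        spec, cross_sim.PoolSpec(depth=40), outdir, seed=11, n_sites=400,
        deletion=("Chr1", 1_500_001, 1_523_500),
    )


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
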