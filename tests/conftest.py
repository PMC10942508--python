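from dataclasses import replace

import pytest

from evidenceyield.simulate import GeneratorConfig, generate_cohort, write_fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-proband cohort under the default (disease-gene) conditions."""
    cfg = replace(GeneratorConfig(), n_probands=12)
    return generate_cohort(cfg, 421)


@pytest.fixture(scope="session")
def small_fixtures(small_cohort, tmp_path_factory):
    """The same cohort written out as VCF/TSV fixture files."""
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(small_cohort, out)


HANDMADE_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=AF,Number=A,Type=Float,Description="Global allele frequency">
##INFO=<ID=AF_nfe,Number=A,Type=Float,Description="nfe allele frequency">
##INFO=<ID=AF_fin,Number=A,Type=Float,Description="fin allele frequency">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Consequence|SYMBOL|Feature|MANE_SELECT">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t100\t.\tA\tG\t100\tPASS\tAF=0.001;AF_nfe=0.002;CSQ=missense_variant|GENEA|ENST01|NM_1.1\tGT:GQ:DP:AD\t0/1:50:10:3,7
chr1\t200\t.\tA\tG,T\t100\tPASS\tAF=0.001,0.002;CSQ=missense_variant|GENEA|ENST01|NM_1.1\tGT:GQ:DP:AD\t1/2:60:20:0,9,11
chr1\t300\t.\tC\tT\t100\tPASS\tAF=0.001;CSQ=missense_variant|GENEA|ENST01|NM_1.1\tGT:DP:AD\t0/1:12:5,7
chr1\t400\t.\tG\tA\t100\tPASS\tCSQ=synonymous_variant|GENEB|ENST02|NM_2.1,missense_variant|GENEB|ENST03|\tGT:GQ:DP:AD\t0/1:80:30:15,15
chr1\t500\t.\tT\tC\t100\tPASS\tAF=0.001;CSQ=missense_variant|GENEC|ENST04|\tGT:GQ:DP:AD\t0/1:80:30:15,15
chr1\t600\t.\tA\tC\t100\tPASS\tAF=0.001;CSQ=stop_gained|GENED|ENST05|NM_5.1,missense_variant|GENED|ENST06|\tGT:GQ:DP:AD\t1/1:80:30:1,29
chr1\t700\t.\tA\tG\t100\tPASS\tAF=0.001;AF_fin=0.2;CSQ=missense_variant|GENEE|ENST07|NM_7.1\tGT:GQ:DP:AD\t0/1:80:30:15,15
"""


@pytest.fixture()
def handmade_vcf(tmp_path):
    path = tmp_path / "S1.vcf"
    path.write_text(HANDMADE_VCF)
    return str(path)
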