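import io

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from poolgwas import io_formats  # noqa: E402

INTENSITY_TSV = """\
snp_id\tchrom\tpos\tpool\treplicate\tgreen\tred
rs1\t1\t1000\tcase\t1\t300\t100
rs1\t1\t1000\tcase\t2\t290\t110
rs1\t1\t1000\tcase\t3\t310\t90
rs1\t1\t1000\tcontrol\t1\t200\t200
rs1\t1\t1000\tcontrol\t2\t210\t190
rs1\t1\t1000\tcontrol\t3\t190\t210
"""

BED_TEXT = """\
chr22\t33160000\t33260000\tTIMP3\t0\t+
chr2\t500\t900\tGENEB\t0\t-
chr1\t100\t200\tGENEA
"""

GMT_TEXT = """\
pathA\tna\tg1\tg2\tg3
pathB\tna\tg2\tg4\tg5\tg5
"""

GENOTYPE_TSV = """\
subject\tgroup\tsnp1\tsnp2
s1\tcase\t0\t1
s2\tcase\t1\tNA
s3\tcontrol\t2\t0
s4\tcontrol\t0\t0
"""

# Validation-cohort genotype counts (n0, n1, n2) as printed for the three
# genotyped loci, cases then controls.
TABLE2_COUNTS = {
    "rs117503120": ((235, 15, 0), (215, 35, 0)),
    "rs5998634": ((212, 36, 2), (238, 12, 0)),
    "rs16866133": ((247, 3, 0), (235, 15, 0)),
}

# response vs nonresponse genotype counts for the treatment-response stage
TABLE3_COUNTS = {
    "rs117503120": ((114, 6, 0), (62, 1, 0)),
    "rs5998634": ((89, 30, 1), (59, 4, 0)),
    "rs16866133": ((119, 4, 0), (63, 0, 0)),
}

# the four genome-wide discovery p-values as printed
DISCOVERY_P = {
    "rs117503120": 6.45e-9,
    "rs4483616": 8.84e-9,
    "rs5998634": 8.06e-8,
    "rs16866133": 9.39e-8,
}


@pytest.fixture
def intensity_table():
    return io_formats.read_pool_intensities(io.StringIO(INTENSITY_TSV))


@pytest.fixture
def gene_annotation():
    return io_formats.read_gene_annotation(io.StringIO(BED_TEXT))


@pytest.fixture
def pathway_db():
    return io_formats.read_gmt(io.StringIO(GMT_TEXT))


@pytest.fixture
def genotype_cohort():
    return io_formats.read_genotypes(io.StringIO(GENOTYPE_TSV))


@pytest.fixture
def table2_counts():
    return TABLE2_COUNTS


@pytest.fixture
def table3_counts():
    return TABLE3_COUNTS


@pytest.fixture
def discovery_p():
    return DISCOVERY_P
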