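import pytest

from metatrio.io_formats import GeneInterval, GeneModelSet, VariantRecord
from metatrio.synthetic import TrioConfig, synthetic_signature_matrix

#: a compact two-chromosome genome so interval/position tests hit things
SMALL_GENOME = {"1": 2_000_000, "2": 2_000_000}


@pytest.fixture(scope="session")
def W5():
    return synthetic_signature_matrix(n_signatures=5, seed=11)


@pytest.fixture(scope="session")
def W30():
    return synthetic_signature_matrix()


@pytest.fixture()
def small_models():
    """One coding gene (UTR5/CDS/intron/CDS/UTR3), one ncRNA gene."""
    models = GeneModelSet()
    for start, end, cls in (
        (1_000, 1_199, "UTR5"),
        (1_200, 1_499, "CDS"),
        (1_500, 2_499, "intron"),
        (2_500, 2_799, "CDS"),
        (2_800, 3_399, "UTR3"),
    ):
        models.add(GeneInterval("1", start, end, "+", "GENE_A", cls))
    models.add(GeneInterval("1", 50_000, 51_999, "-", "NC_B", "ncRNA_exon"))
    return models


def snv(chrom="1", pos=100, ref="C", alt="T", sample="s1", ref_count=30,
        alt_count=10, somatic=True, context=None):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         sample_id=sample, ref_count=ref_count,
                         alt_count=alt_count, caller_somatic=somatic,
                         context=context)


@pytest.fixture()
def make_snv():
    return snv


#: stratum exposures over a 5-signature matrix (AC1..AC5)
EXPOSURES5 = {
    "truncal": {"AC1": 0.6, "AC5": 0.4},
    "tumor_private": {"AC1": 0.5, "AC3": 0.5},
    "met_private": {"AC3": 0.6, "AC5": 0.4},
}


@pytest.fixture()
def small_trio_config():
    return TrioConfig(
        n_snvs=1_500,
        n_germline_hets=400,
        exposures={s: dict(e) for s, e in EXPOSURES5.items()},
        genome=dict(SMALL_GENOME) | {"3": 2_000_000},
        seed=5,
    )
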