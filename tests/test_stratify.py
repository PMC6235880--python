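"""Trio stratification: rescue rules, Poisson support model, invariants."""

import math
from dataclasses import replace

import pytest

from metatrio.annotate import AnnotatedVariant
from metatrio.stratify import (
    TrioDataset,
    assign_stratum,
    classify_sample_msi_pole,
    expected_read_support,
    min_alt_reads_for_maf,
    mutation_rate_per_mb,
    poisson_support_probability,
    rescue_in_pair,
    stratify_trio,
)
from metatrio.synthetic import TrioConfig, generate_trio

from conftest import EXPOSURES5, SMALL_GENOME, snv


class TestExpectedReadSupport:
    def test_cohort_median_gives_5_7_reads(self):
        assert expected_read_support(0.475, 36, 3) == pytest.approx(5.7)

    @pytest.mark.parametrize("purity,cov,ploidy,expected", [
        (1.0, 30, 2, 15.0),
        (0.5, 40, 4, 5.0),
    ])
    def test_simple_values(self, purity, cov, ploidy, expected):
        assert expected_read_support(purity, cov, ploidy) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            expected_read_support(0.0, 36, 3)


class TestPoissonSupport:
    def test_closed_form_values(self):
        assert poisson_support_probability(0, 1.0) == pytest.approx(math.exp(-1))
        # direct pmf evaluation at the 2-read support point, mu = 5.7
        expected = math.exp(-5.7) * 5.7**2 / 2
        assert poisson_support_probability(2, 5.7) == pytest.approx(expected)
        assert poisson_support_probability(2, 5.7) == pytest.approx(0.0544, abs=5e-4)
        assert poisson_support_probability(2, 2.0) == pytest.approx(0.2707, abs=5e-5)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            poisson_support_probability(-1, 2.0)


class TestMinAltReads:
    @pytest.mark.parametrize("cov,thr,expected", [
        (36, 0.05, 2),    # the 2-read floor at series coverage
        (100, 0.05, 6),   # frozen from exhaustive search over r
        (20, 0.5, 11),    # frozen from exhaustive search over r
    ])
    def test_examples(self, cov, thr, expected):
        assert min_alt_reads_for_maf(cov, thr) == expected

    def test_result_is_minimal(self):
        for cov in (7, 36, 121):
            for thr in (0.02, 0.05, 0.31):
                r = min_alt_reads_for_maf(cov, thr)
                assert r / cov > thr
                assert (r - 1) / cov <= thr


def make_trio(tumor=None, met=None, normal=None, **kwargs):
    defaults = dict(patient_id="P", purity_tumor=0.6, purity_met=0.6,
                    ploidy_tumor=2.0, ploidy_met=2.0)
    defaults.update(kwargs)
    as_dict = lambda recs: {r.key: r for r in (recs or [])}
    return TrioDataset(normal=as_dict(normal), tumor=as_dict(tumor),
                       metastasis=as_dict(met), **defaults)


class TestRescueInPair:
    def test_rescued_when_all_rules_met(self):
        trio = make_trio(
            tumor=[snv(alt_count=12, ref_count=24, somatic=True)],
            met=[snv(sample="m", ref_count=36, alt_count=4, somatic=False)],
            normal=[snv(sample="n", ref_count=49, alt_count=1, somatic=False)],
        )
        # met MAF 0.10 > 0.05, alt 4 >= 2, 0.10 >= 2 x control 0.02
        assert rescue_in_pair(snv().key, trio) == (True, True)

    def test_below_maf_threshold_not_rescued(self):
        trio = make_trio(
            tumor=[snv(alt_count=12, ref_count=24)],
            met=[snv(sample="m", ref_count=48, alt_count=2, somatic=False)],
        )
        assert rescue_in_pair(snv().key, trio) == (True, False)

    def test_germline_ratio_blocks_rescue(self):
        trio = make_trio(
            tumor=[snv(alt_count=12, ref_count=24)],
            met=[snv(sample="m", ref_count=36, alt_count=4, somatic=False)],
            normal=[snv(sample="n", ref_count=47, alt_count=3, somatic=False)],
        )
        # met MAF 0.10 < 2 x control MAF 0.06
        assert rescue_in_pair(snv().key, trio) == (True, False)

    def test_zero_control_maf_satisfies_ratio(self):
        trio = make_trio(
            tumor=[snv(alt_count=12, ref_count=24)],
            met=[snv(sample="m", ref_count=30, alt_count=6, somatic=False)],
            normal=[snv(sample="n", ref_count=50, alt_count=0, somatic=False)],
        )
        assert rescue_in_pair(snv().key, trio) == (True, True)

    def test_absent_from_both_is_error(self):
        trio = make_trio(tumor=[snv(somatic=False)])
        with pytest.raises(ValueError):
            rescue_in_pair(snv().key, trio)


class TestAssignStratum:
    @pytest.mark.parametrize("flags,expected", [
        ((True, True), "shared"),
        ((True, False), "tumor_private"),
        ((False, True), "met_private"),
    ])
    def test_mapping(self, flags, expected):
        assert assign_stratum(*flags) == expected

    def test_neither_is_error(self):
        with pytest.raises(ValueError):
            assign_stratum(False, False)


@pytest.fixture()
def noisy_trio(W5):
    cfg = TrioConfig(n_snvs=4_000, contamination_fraction=0.0, n_germline_hets=0,
                     exposures={s: dict(e) for s, e in EXPOSURES5.items()},
                     genome=dict(SMALL_GENOME) | {"3": 2_000_000, "4": 2_000_000},
                     seed=17)
    return generate_trio(cfg, W5)


class TestStratifyTrio:
    def test_fractions_partition(self, noisy_trio):
        trio, _ = noisy_trio
        result = stratify_trio(trio)
        assert result.f_shared + result.f_tumor + result.f_met == pytest.approx(1.0)
        assert len(result.assignments) == result.n_snvs

    def test_symmetry_under_sample_swap(self, noisy_trio):
        trio, _ = noisy_trio
        a = stratify_trio(trio)
        b = stratify_trio(trio.swapped())
        assert a.f_shared == pytest.approx(b.f_shared)
        assert a.f_tumor == pytest.approx(b.f_met)
        assert a.f_met == pytest.approx(b.f_tumor)

    def test_rescue_monotone_in_maf_threshold(self, noisy_trio):
        trio, _ = noisy_trio
        shared = [
            stratify_trio(trio, maf_threshold=thr).f_shared
            for thr in (0.02, 0.05, 0.10, 0.20, 0.40)
        ]
        assert shared == sorted(shared, reverse=True)

    def test_recall_against_truth(self, noisy_trio):
        trio, truth = noisy_trio
        result = stratify_trio(trio)
        mapping = {"truncal": "shared", "tumor_private": "tumor_private",
                   "met_private": "met_private"}
        agree = sum(
            result.assignments.get(k) == mapping[s]
            for k, s in truth.stratum.items()
        )
        assert agree / len(truth.stratum) >= 0.95

    def test_halved_metastasis_coverage_rescue_compensates(self, W5):
        base = TrioConfig(n_snvs=4_000, contamination_fraction=0.0,
                          n_germline_hets=0,
                          exposures={s: dict(e) for s, e in EXPOSURES5.items()},
                          genome=dict(SMALL_GENOME), seed=23)
        halved = replace(base, coverage_met=18.0)
        f_full = stratify_trio(generate_trio(base, W5)[0]).f_shared
        f_half = stratify_trio(generate_trio(halved, W5)[0]).f_shared
        assert abs(f_full - f_half) < 0.03

    def test_empty_somatic_set_is_error(self):
        trio = make_trio(tumor=[snv(somatic=False)], met=[], normal=[])
        with pytest.raises(ValueError):
            stratify_trio(trio)


class TestMutationRate:
    def test_paper_value(self):
        assert mutation_rate_per_mb(17_189, 2.8e9) == 6.1

    @pytest.mark.parametrize("n,expected", [(0, 0.0), (2_800, 1.0)])
    def test_simple(self, n, expected):
        assert mutation_rate_per_mb(n, 2.8e9) == expected


class TestMsiPoleFlags:
    def _av(self, gene, region="CDS", non_silent=True):
        return AnnotatedVariant(snv(), region, (gene,), "not_applicable", non_silent)

    def test_no_hits(self):
        flags = classify_sample_msi_pole([self._av("KRAS")])
        assert flags == {"mmr_hit": False, "pole_hit": False}

    def test_msh2_hit(self):
        flags = classify_sample_msi_pole([self._av("MSH2")])
        assert flags["mmr_hit"] and not flags["pole_hit"]

    def test_pole_utr3_does_not_count(self):
        flags = classify_sample_msi_pole(
            [self._av("POLE", region="UTR3", non_silent=False)]
        )
        assert not flags["pole_hit"]

    def test_pole_nonsilent_counts(self):
        assert classify_sample_msi_pole([self._av("POLE")])["pole_hit"]
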