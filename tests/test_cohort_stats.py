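"""Recurrence matrices, exclusivity, exact tests vs enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metatrio.annotate import AnnotatedVariant
from metatrio.cohort_stats import (
    bh_adjust,
    build_mutation_matrix,
    chi2_test_2x2,
    fisher_exact_2x2,
    hypergeometric_enrichment,
    mutual_exclusivity,
    recurrent_genes,
)

from conftest import snv


def av(gene, region="CDS", non_silent=True, pos=100):
    return AnnotatedVariant(snv(pos=pos), region, (gene,), "not_applicable",
                            non_silent)


def fisher_enumeration_oracle(table):
    """Sum hypergeometric probabilities of all margin-fixed tables whose
    probability does not exceed the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return 1.0

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def bh_stepup_oracle(pvals):
    """q_(i) = min_{j >= i} m p_(j) / j, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestMutationMatrix:
    def test_duplicates_collapse(self):
        matrix = build_mutation_matrix(
            {"s1": [av("g1", pos=10), av("g1", pos=20)]}, "coding_nonsilent"
        )
        assert matrix.loc["g1", "s1"] == 1

    def test_channel_filters(self):
        annotated = {"s1": [av("g1", region="UTR3", non_silent=False)]}
        coding = build_mutation_matrix(annotated, "coding_nonsilent")
        utr = build_mutation_matrix(annotated, "UTR3")
        assert coding.empty and utr.loc["g1", "s1"] == 1

    def test_empty_cohort(self):
        assert build_mutation_matrix({}, "ncRNA").shape == (0, 0)

    def test_unknown_channel(self):
        with pytest.raises(ValueError, match="channel"):
            build_mutation_matrix({}, "promoter")


class TestRecurrentGenes:
    def _matrix(self):
        return pd.DataFrame(
            {"s1": [1, 1, 0], "s2": [1, 1, 0], "s3": [1, 0, 1], "s4": [1, 0, 0]},
            index=["apc", "tp53", "zzz"],
        )

    def test_cutoff_applied(self):
        out = recurrent_genes(self._matrix(), min_samples=4)
        assert out.gene.tolist() == ["apc"]

    def test_min_one_returns_all(self):
        assert len(recurrent_genes(self._matrix(), min_samples=1)) == 3

    def test_ties_alphabetical(self):
        m = pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["b", "a"])
        assert recurrent_genes(m, 1).gene.tolist() == ["a", "b"]


class TestMutualExclusivity:
    def _matrix(self, a_samples, b_samples, n=12):
        cols = [f"s{i}" for i in range(1, n + 1)]
        m = pd.DataFrame(0, index=["A", "B"], columns=cols)
        m.loc["A", [f"s{i}" for i in a_samples]] = 1
        m.loc["B", [f"s{i}" for i in b_samples]] = 1
        return m

    def test_disjoint_is_exclusive(self):
        out = mutual_exclusivity(self._matrix([1, 2, 3], [4, 5, 6]), "A", "B")
        assert out["overlap"] == 0 and out["exclusive"]

    def test_single_overlap_still_exclusive(self):
        out = mutual_exclusivity(self._matrix([1, 2], [2, 3]), "A", "B")
        assert out["overlap"] == 1 and out["exclusive"]

    def test_two_overlaps_not_exclusive(self):
        out = mutual_exclusivity(self._matrix([1, 2, 3], [1, 2, 4]), "A", "B")
        assert out["overlap"] == 2 and not out["exclusive"]

    def test_symmetric(self):
        m = self._matrix([1, 2, 3], [2, 5])
        ab = mutual_exclusivity(m, "A", "B")
        ba = mutual_exclusivity(m, "B", "A")
        assert ab["fisher_p"] == ba["fisher_p"]
        assert ab["overlap"] == ba["overlap"]

    def test_absent_gene_error(self):
        with pytest.raises(ValueError, match="not in"):
            mutual_exclusivity(self._matrix([1], [2]), "A", "C")


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[3, 0], [0, 3]], 0.1),       # 2 / C(6,3)
        ([[1, 1], [1, 1]], 1.0),
        ([[2, 0], [0, 2]], 1 / 3),     # 2 / C(4,2)
    ])
    def test_enumeration_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_is_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            t = rng.integers(0, 11, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_enumeration_oracle(t), rel=1e-9
            )


class TestChi2:
    def test_identical_rows_p_one(self):
        assert chi2_test_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association(self):
        # statistic 20 at df=1
        assert chi2_test_2x2([[10, 0], [0, 10]]) == pytest.approx(7.744e-6, rel=1e-3)

    def test_statistic_four_gives_0_0455(self):
        # [[2,6],[6,2]] has expected 4 everywhere: chi2 = 4 * (4/4) = 4.0
        assert chi2_test_2x2([[2, 6], [6, 2]]) == pytest.approx(0.0455, abs=5e-5)

    def test_zero_expected_errors_advising_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi2_test_2x2([[0, 0], [3, 5]])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("pvals,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.01, 0.04], [0.02, 0.04]),
    ])
    def test_stepup_examples(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), bh_stepup_oracle(pvals), rtol=1e-10, atol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p_and_monotone(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestHypergeometricEnrichment:
    def test_full_overlap_small_universe(self):
        universe = [f"g{i}" for i in range(10)]
        gene_set = universe[:5]
        p = hypergeometric_enrichment(gene_set, gene_set, universe)
        assert p == pytest.approx(1 / 252)  # C(5,5)/C(10,5)

    def test_empty_intersection_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        p = hypergeometric_enrichment(universe[:3], universe[5:], universe)
        assert p == pytest.approx(1.0)

    def test_hits_equal_universe_forced(self):
        universe = [f"g{i}" for i in range(6)]
        assert hypergeometric_enrichment(universe, universe[:2], universe) == \
            pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment(["x"], ["g1"], ["g1", "g2"])
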