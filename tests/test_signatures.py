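"""Catalog building, NNLS decomposition, cutoffs, strata comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import lsq_linear

from metatrio.contexts import CONTEXT_INDEX
from metatrio.signatures import (
    Catalog96,
    ExposureVector,
    apply_signature_cutoffs,
    associate_exposure_with_group,
    build_catalog,
    cluster_exposures,
    cohort_signature_detection,
    compare_strata_exposures,
    nnls_decompose,
)
from metatrio.synthetic import generate_catalog_from_exposures

from conftest import snv


def qp_oracle(W, counts):
    """Independent bounded least-squares solve (BVLS active-set)."""
    res = lsq_linear(W, counts, bounds=(0, np.inf), method="bvls", tol=1e-14)
    return res.x


class TestBuildCatalog:
    def test_pyrimidine_snv_binned_directly(self):
        cat = build_catalog([snv(ref="C", alt="A", context="ACA")])
        assert cat.counts[CONTEXT_INDEX["A[C>A]A"]] == 1
        assert cat.total == 1

    def test_purine_snv_reverse_complemented(self):
        cat = build_catalog([snv(ref="G", alt="T", context="TGT")])
        assert cat.counts[CONTEXT_INDEX["A[C>A]A"]] == 1

    def test_empty_input_all_zero(self):
        cat = build_catalog([])
        assert cat.total == 0

    def test_context_with_n_skipped_and_reported(self):
        cat = build_catalog([
            snv(ref="C", alt="A", context="ACA"),
            snv(pos=2, ref="C", alt="A", context="NCA"),
        ])
        assert cat.total == 1 and cat.skipped == 1

    def test_missing_context_is_error(self):
        with pytest.raises(ValueError, match="context"):
            build_catalog([snv(ref="C", alt="A")])


class TestNnlsDecompose:
    def test_exact_two_signature_mixture(self, W5):
        counts = 30 * W5.W[:, 0] + 70 * W5.W[:, 1]
        ev = nnls_decompose(Catalog96(counts), W5)
        np.testing.assert_allclose(ev.exposures, [30, 70, 0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(ev.normalized[:2], [0.3, 0.7], atol=1e-10)

    def test_single_signature(self, W5):
        ev = nnls_decompose(Catalog96(100 * W5.W[:, 0]), W5)
        np.testing.assert_allclose(ev.exposures, [100, 0, 0, 0, 0], atol=1e-9)
        assert ev.residual == pytest.approx(0.0, abs=1e-9)

    def test_matches_qp_oracle_on_random_catalogs(self, W5):
        rng = np.random.default_rng(42)
        for _ in range(25):
            counts = rng.poisson(50, size=96).astype(float)
            ev = nnls_decompose(Catalog96(counts), W5)
            np.testing.assert_allclose(ev.exposures, qp_oracle(W5.W, counts),
                                       atol=1e-6)

    def test_zero_catalog_rejected(self, W5):
        with pytest.raises(ValueError, match="skip"):
            nnls_decompose(Catalog96(np.zeros(96)), W5)

    def test_scale_equivariance(self, W5):
        rng = np.random.default_rng(7)
        counts = rng.poisson(40, size=96).astype(float)
        a = nnls_decompose(Catalog96(counts), W5)
        b = nnls_decompose(Catalog96(3.5 * counts), W5)
        np.testing.assert_allclose(b.exposures, 3.5 * a.exposures, rtol=1e-8)
        np.testing.assert_allclose(b.normalized, a.normalized, atol=1e-10)

    def test_local_optimality_of_solution(self, W5):
        rng = np.random.default_rng(8)
        counts = rng.poisson(40, size=96).astype(float)
        ev = nnls_decompose(Catalog96(counts), W5)
        base = np.linalg.norm(counts - W5.W @ ev.exposures)
        for i in range(5):
            for eps in (1e-4, -1e-4):
                e = ev.exposures.copy()
                e[i] = max(0.0, e[i] + eps)
                assert np.linalg.norm(counts - W5.W @ e) >= base - 1e-12


def cutoff_subset_oracle(counts, W, cutoff):
    """Best admissible fit by exhaustive search over signature subsets."""
    S = W.W.shape[1]
    best, best_resid = None, np.inf
    for r in range(1, S + 1):
        for subset in itertools.combinations(range(S), r):
            Wsub = W.W[:, list(subset)]
            e = qp_oracle(Wsub, counts)
            if e.sum() == 0:
                continue
            norm = e / e.sum()
            if np.any(norm < cutoff - 1e-12):
                continue
            resid = np.linalg.norm(counts - Wsub @ e)
            if resid < best_resid - 1e-9:
                best_resid = resid
                best = dict(zip(subset, e))
    full = np.zeros(S)
    for i, v in (best or {}).items():
        full[i] = v
    return full


class TestSignatureCutoffs:
    def test_zero_cutoffs_identity(self, W5):
        rng = np.random.default_rng(1)
        cat = Catalog96(rng.poisson(30, size=96).astype(float))
        ev = nnls_decompose(cat, W5)
        out = apply_signature_cutoffs(ev, 0.0, cat, W5)
        np.testing.assert_allclose(out.exposures, ev.exposures)

    def test_minor_signature_removed_and_refit(self, W5):
        counts = 970 * W5.W[:, 0] + 30 * W5.W[:, 1]
        cat = Catalog96(counts)
        ev = nnls_decompose(cat, W5)
        out = apply_signature_cutoffs(ev, 0.05, cat, W5)
        assert out.exposures[1] == 0.0
        assert out.exposures[0] > 0

    def test_matches_subset_search_oracle(self, W5):
        rng = np.random.default_rng(19)
        for _ in range(8):
            e_true = rng.dirichlet([0.5] * 5) * 1000
            counts = np.round(W5.W @ e_true + rng.normal(0, 2, 96)).clip(0)
            cat = Catalog96(counts)
            out = apply_signature_cutoffs(nnls_decompose(cat, W5), 0.08, cat, W5)
            oracle = cutoff_subset_oracle(counts, W5, 0.08)
            np.testing.assert_allclose(out.exposures, oracle, atol=1e-5)

    def test_all_removed_warns_and_zeroes(self, W5):
        cat = Catalog96(100 * W5.W[:, 0])
        ev = nnls_decompose(cat, W5)
        with pytest.warns(UserWarning, match="all signatures removed"):
            out = apply_signature_cutoffs(ev, 1.1, cat, W5)
        assert out.total == 0.0

    def test_raising_cutoff_never_adds_signatures(self, W5):
        rng = np.random.default_rng(29)
        cat = Catalog96(rng.poisson(60, size=96).astype(float))
        ev = nnls_decompose(cat, W5)
        prev = None
        for cutoff in (0.0, 0.05, 0.1, 0.2, 0.4):
            active = {
                s for s, e in zip(
                    W5.signature_ids,
                    apply_signature_cutoffs(ev, cutoff, cat, W5).exposures,
                ) if e > 0
            }
            if prev is not None:
                assert active <= prev
            prev = active


class TestCohortDetection:
    def test_generating_signatures_recovered(self, W5):
        cats = [
            generate_catalog_from_exposures(W5, [0.6, 0, 0, 0, 0.4], 5_000, seed=s)
            for s in range(4)
        ]
        active = cohort_signature_detection(cats, W5, 0.01)
        assert set(active) == {"AC1", "AC5"}

    def test_single_catalog_equals_per_sample_fit(self, W5):
        cat = generate_catalog_from_exposures(W5, [0.5, 0.5, 0, 0, 0], 3_000, seed=1)
        active = cohort_signature_detection([cat], W5, 0.05)
        fit = apply_signature_cutoffs(nnls_decompose(cat, W5), 0.05, cat, W5)
        per_sample = {s for s, e in zip(W5.signature_ids, fit.exposures) if e > 0}
        assert set(active) == per_sample

    def test_impossible_cutoffs_error(self, W5):
        cat = generate_catalog_from_exposures(W5, [1, 0, 0, 0, 0], 1_000, seed=2)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                cohort_signature_detection([cat], W5, 1.1)

    def test_empty_cohort_error(self, W5):
        with pytest.raises(ValueError, match="empty"):
            cohort_signature_detection([], W5)


def _exposure(ids, values):
    values = np.asarray(values, dtype=float)
    return ExposureVector(ids, values, 0.0)


class TestCompareStrata:
    ids = ("S1", "S2")

    def _patients(self, diffs):
        """met_private S1 exposure shifted by per-patient diffs."""
        out = {}
        for i, d in enumerate(diffs):
            base = 0.5
            out[f"P{i}"] = {
                "shared": _exposure(self.ids, [base, 1 - base]),
                "tumor_private": _exposure(self.ids, [base, 1 - base]),
                "met_private": _exposure(self.ids, [base + d, 1 - base - d]),
            }
        return out

    def test_identical_exposures_give_p_one(self):
        table = compare_strata_exposures(self._patients([0.0] * 5))
        assert (table["p"] == 1.0).all()

    def test_consistent_shift_matches_exact_wilcoxon(self):
        # signature S1 higher in met_private for all 8 patients: the exact
        # two-sided signed-rank p for a uniform sign pattern is 2/2^8
        diffs = [0.05 + 0.01 * i for i in range(8)]
        table = compare_strata_exposures(self._patients(diffs))
        row = table[(table.pair == "met_private_vs_shared") &
                    (table.signature == "S1")].iloc[0]
        assert row.p == pytest.approx(2 / 2**8)
        assert row.median_diff > 0

    def test_exact_p_cross_checked_by_sign_flip_enumeration(self):
        diffs = [0.05, 0.02, -0.01, 0.04, 0.03, 0.06]
        table = compare_strata_exposures(self._patients(diffs))
        row = table[(table.pair == "met_private_vs_shared") &
                    (table.signature == "S1")].iloc[0]
        # enumerate all sign assignments of the ranked |d|
        d = np.array(diffs)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        n = len(d)
        stats = []
        for mask in itertools.product([0, 1], repeat=n):
            stats.append((ranks * np.array(mask)).sum())
        stats = np.array(stats)
        mean_w = n * (n + 1) / 4
        p_exact = np.mean(np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        assert row.p == pytest.approx(p_exact)

    def test_fewer_than_three_patients_error(self):
        with pytest.raises(ValueError, match="3 patients"):
            compare_strata_exposures(self._patients([0.1, 0.2]))


def linkage_heights_oracle(X):
    """Naive O(n^3) complete-linkage agglomeration; returns merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    np.linalg.norm(X[a] - X[b])
                    for a in clusters[i] for b in clusters[j]
                )
                if d < best[0] - 1e-15:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return np.array(heights)


class TestClusterExposures:
    def test_identical_rows_merge_first_at_zero(self):
        X = pd.DataFrame([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]],
                         index=["a", "b", "c"])
        order, Z = cluster_exposures(X)
        assert Z[0, 2] == 0.0
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(33)
        X = rng.random((8, 5))
        _, Z = cluster_exposures(pd.DataFrame(X))
        np.testing.assert_allclose(
            np.sort(Z[:, 2]), np.sort(linkage_heights_oracle(X)), atol=1e-10
        )

    def test_deterministic_leaf_order(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((6, 3)))
        assert cluster_exposures(X)[0] == cluster_exposures(X)[0]


class TestAssociateWithGroup:
    def test_identical_values_p_one(self):
        df = pd.DataFrame({"S1": [0.3] * 6})
        out = associate_exposure_with_group(df, [True] * 3 + [False] * 3)
        assert out.loc[0, "p"] == 1.0

    def test_perfect_separation_exact_p(self):
        df = pd.DataFrame({"S1": [1, 2, 3, 4, 10, 11, 12, 13]})
        out = associate_exposure_with_group(df, [False] * 4 + [True] * 4)
        assert out.loc[0, "p"] == pytest.approx(2 / 70)  # 2 / C(8,4)

    def test_single_observation_each_p_one(self):
        df = pd.DataFrame({"S1": [1.0, 2.0]})
        out = associate_exposure_with_group(df, [True, False])
        assert out.loc[0, "p"] == 1.0

    def test_empty_group_error(self):
        df = pd.DataFrame({"S1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            associate_exposure_with_group(df, [True, True])
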