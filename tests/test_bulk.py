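"""Derivation-chain operations: split, normalise, DE, filters, scoring."""

import numpy as np
import pandas as pd
import pytest

from metsig import bulk
from metsig.bulk import (
    EmptySignatureError,
    MetSigScorer,
    correlation_filter,
    de_test,
    derive_signature,
    intersect_degs,
    kmeans_coexpression,
    metsig_score,
    normalize_counts,
    split_by_anchor,
    tf_target_filter,
)
from metsig.datamodel import ExpressionMatrix, SignatureDefinition
from metsig.simulate import BulkSimSpec, simulate_bulk_cohort
from metsig.stats import zscore_rows


def _em(values, genes=None, unit="log_normalized"):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])]),
        unit=unit,
    )


class TestSplitByAnchor:
    def test_mean_split_strictly_above(self):
        m = _em([10.0, 20.0, 30.0, 40.0], genes=["CDC42"])
        labels = split_by_anchor(m, "CDC42")
        assert list(labels) == ["lo", "lo", "hi", "hi"]

    def test_constant_anchor_all_lo_with_warning(self):
        m = _em([7.0, 7.0, 7.0], genes=["CDC42"])
        with pytest.warns(UserWarning, match="constant"):
            labels = split_by_anchor(m, "CDC42")
        assert set(labels) == {"lo"}

    def test_random_vector_matches_brute_force(self, rng):
        vals = rng.gamma(3.0, 10.0, size=25)
        m = _em(vals, genes=["CDC42"])
        labels = split_by_anchor(m, "CDC42")
        assert (labels == "hi").sum() == int((vals > vals.mean()).sum())

    def test_missing_anchor_named(self, small_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            split_by_anchor(small_matrix, "NOPE")


class TestNormalizeCounts:
    def test_doubled_column_equalised(self):
        counts = np.array([[10.0, 20.0], [4.0, 8.0], [100.0, 200.0]])
        norm = normalize_counts(_em(counts, unit="raw_counts"))
        np.testing.assert_allclose(
            norm.data.iloc[:, 0], norm.data.iloc[:, 1], rtol=1e-12
        )

    def test_identical_columns_unit_factors(self):
        counts = np.tile(np.array([[7.0], [3.0], [90.0]]), (1, 4))
        norm = normalize_counts(_em(counts, unit="raw_counts"))
        np.testing.assert_allclose(norm.data.to_numpy(), np.log2(counts + 1), rtol=1e-12)

    def test_size_factors_match_independent_median_of_ratios(self, rng):
        counts = rng.integers(1, 500, size=(30, 5)).astype(float)
        norm = normalize_counts(_em(counts, unit="raw_counts"))
        # independent recomputation
        ref = np.exp(np.log(counts).mean(axis=1))
        sf = np.median(counts / ref[:, None], axis=0)
        np.testing.assert_allclose(
            norm.data.to_numpy(), np.log2(counts / sf + 1), rtol=1e-10
        )

    def test_zero_everywhere_falls_back_to_library_size(self):
        counts = np.array([[0.0, 10.0], [4.0, 0.0]])
        with pytest.warns(UserWarning, match="library-size"):
            norm = normalize_counts(_em(counts, unit="raw_counts"))
        assert norm.unit == "log_normalized"


class TestDeTest:
    def _labels(self, n_hi, n_lo):
        return pd.Series(
            ["hi"] * n_hi + ["lo"] * n_lo,
            index=[f"s{j}" for j in range(n_hi + n_lo)],
        )

    def test_no_signal_gene_gets_p_one(self):
        m = _em([[1.0] * 8], genes=["flat"])
        res = de_test(m, self._labels(4, 4))
        assert res.loc[0, "log2_fold_change"] == 0.0
        assert res.loc[0, "p_value"] == 1.0

    def test_exact_separation_gets_smallest_positive_p(self):
        m = _em([[2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0]], genes=["sep"])
        res = de_test(m, self._labels(4, 4))
        assert res.loc[0, "log2_fold_change"] == pytest.approx(1.0)
        assert 0 < res.loc[0, "p_value"] <= np.finfo(float).tiny

    def test_small_group_rejected(self):
        m = _em([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError):
            de_test(m, self._labels(2, 2))


class TestIntersectDegs:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "p_value"])

    def test_set_arithmetic_and_fractions(self):
        a = self._df([("A", 1, 0.01), ("B", 1, 0.01), ("C", 1, 0.01), ("D", 1, 0.5)])
        b = self._df([("B", 2, 0.02), ("C", 0.5, 0.02), ("D", 1, 0.01), ("A", 1, 0.9)])
        common, fa, fb = intersect_degs(a, b, alpha=0.05)
        assert common == {"B", "C"}
        assert fa == pytest.approx(2 / 3)
        assert fb == pytest.approx(2 / 3)

    def test_opposite_signs_excluded(self):
        a = self._df([("A", 1.0, 0.001)])
        b = self._df([("A", -1.0, 0.001)])
        common, _, _ = intersect_degs(a, b)
        assert common == set()

    def test_up_direction_drops_downregulated(self):
        a = self._df([("A", -1.0, 0.001), ("B", 1.0, 0.001)])
        b = self._df([("A", -1.0, 0.001), ("B", 1.0, 0.001)])
        common, _, _ = intersect_degs(a, b, direction="up")
        assert common == {"B"}


class TestKmeansCoexpression:
    def test_anticorrelated_groups_perfectly_separated(self):
        up = [0.0, 1.0, 2.0, 3.0]
        down = [3.0, 2.0, 1.0, 0.0]
        m = zscore_rows(_em([up, up, up, down, down, down]))
        labels = kmeans_coexpression(m, k=2, seed=0)
        assert len(set(labels.iloc[:3])) == 1
        assert len(set(labels.iloc[3:])) == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_duplicate_rows_always_co_clustered(self, rng):
        base = rng.normal(size=(4, 6))
        values = np.vstack([base, base[0]])
        m = zscore_rows(_em(values))
        labels = kmeans_coexpression(m, k=2, seed=1)
        assert labels.iloc[0] == labels.iloc[4]

    def test_k_larger_than_genes_rejected(self, rng):
        m = zscore_rows(_em(rng.normal(size=(3, 5))))
        with pytest.raises(ValueError):
            kmeans_coexpression(m, k=4)


class TestTfTargetFilter:
    def test_union_membership(self):
        tfmap = {"NFE2L1": {"g1"}, "HOXA2": {"g3"}}
        kept = tf_target_filter({"g1", "g2", "g3"}, tfmap, {"NFE2L1", "HOXA2"})
        assert kept == {"g1", "g3"}

    def test_missing_tf_is_an_error(self):
        with pytest.raises(KeyError, match="NFRKB"):
            tf_target_filter({"g1"}, {"NFE2L1": {"g1"}}, {"NFE2L1", "NFRKB"})

    def test_empty_result_warns_not_errors(self):
        with pytest.warns(UserWarning):
            kept = tf_target_filter({"g2"}, {"NFE2L1": {"g1"}}, {"NFE2L1"})
        assert kept == set()

    def test_random_map_matches_brute_force(self, rng):
        genes = {f"g{i}" for i in range(50)}
        tfmap = {
            f"TF{t}": {f"g{i}" for i in rng.integers(0, 50, size=10)} for t in range(4)
        }
        tfs = {"TF0", "TF2"}
        expected = {g for g in genes if any(g in tfmap[t] for t in tfs)}
        assert tf_target_filter(genes, tfmap, tfs) == expected


class TestCorrelationFilter:
    def test_anchor_duplicates_all_retained(self, rng):
        anchor = rng.normal(size=20)
        rows = [anchor, anchor + 1, anchor * 2, anchor - 3]
        m = _em(rows, genes=["CDC42", "c1", "c2", "c3"])
        kept, trace = correlation_filter({"c1", "c2", "c3"}, "CDC42", m)
        assert kept == {"c1", "c2", "c3"}
        assert trace == []

    def test_anticorrelated_candidate_pruned(self, rng):
        anchor = rng.normal(size=20)
        m = _em([anchor, anchor + 0.01 * rng.normal(size=20), -anchor],
                genes=["CDC42", "good", "anti"])
        kept, _ = correlation_filter({"good", "anti"}, "CDC42", m)
        assert kept == {"good"}

    def test_independent_candidate_usually_pruned(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            anchor = rng.normal(size=200)
            coupled = [anchor + 0.3 * rng.normal(size=200) for _ in range(3)]
            indep = rng.normal(size=200)
            m = _em([anchor, *coupled, indep],
                    genes=["CDC42", "c1", "c2", "c3", "indep"])
            kept, _ = correlation_filter({"c1", "c2", "c3", "indep"}, "CDC42", m)
            hits += "indep" not in kept
        assert hits >= 95

    def test_all_pruned_raises_with_trace(self, rng):
        anchor = rng.normal(size=30)
        m = _em([anchor, rng.normal(size=30)], genes=["CDC42", "x"])
        with pytest.raises(EmptySignatureError, match="trace"):
            correlation_filter({"x"}, "CDC42", m, rho_min=0.9)


class TestMetsigScore:
    def test_two_gene_worked_example(self):
        # signature rows [[1,3],[2,6]] z-score to +-1/sqrt(2) each,
        # so the sums are -sqrt(2), +sqrt(2)
        m = _em([[1.0, 3.0], [2.0, 6.0], [5.0, 9.0]], genes=["SIG1", "SIG2", "CDC42"])
        scores = metsig_score(m, SignatureDefinition("CDC42", ["SIG1", "SIG2"]))
        np.testing.assert_allclose(
            scores["metsig"], [-np.sqrt(2), np.sqrt(2)], atol=1e-10
        )

    def test_constant_matrix_scores_zero(self):
        m = _em(np.full((3, 4), 2.0), genes=["SIG1", "SIG2", "CDC42"])
        scores = metsig_score(m, SignatureDefinition("CDC42", ["SIG1", "SIG2"]))
        np.testing.assert_array_equal(scores["metsig"], 0.0)

    def test_gene_order_irrelevant(self, rng):
        values = rng.normal(size=(4, 6))
        genes = ["a", "b", "c", "CDC42"]
        m = _em(values, genes=genes)
        s1 = metsig_score(m, SignatureDefinition("CDC42", ["a", "b", "c"]))
        s2 = metsig_score(m, SignatureDefinition("CDC42", ["c", "a", "b"]))
        np.testing.assert_allclose(s1["metsig"], s2["metsig"], atol=1e-12)

    def test_affine_rescaling_of_genes_absorbed(self, rng):
        values = rng.normal(size=(3, 8))
        m1 = _em(values, genes=["a", "b", "CDC42"])
        m2 = _em(values * np.array([[3.0], [0.5], [7.0]]) + 11.0,
                 genes=["a", "b", "CDC42"])
        sig = SignatureDefinition("CDC42", ["a", "b"])
        np.testing.assert_allclose(
            metsig_score(m1, sig)["metsig"], metsig_score(m2, sig)["metsig"], atol=1e-10
        )

    def test_missing_gene_listed(self, rng):
        m = _em(rng.normal(size=(2, 4)), genes=["a", "CDC42"])
        with pytest.raises(KeyError, match="ghost"):
            metsig_score(m, SignatureDefinition("CDC42", ["a", "ghost"]))

    def test_per_group_standardisation_sums_to_zero_within_group(self, rng):
        values = rng.normal(size=(3, 10))
        m = _em(values, genes=["a", "b", "CDC42"])
        groups = pd.Series(["X"] * 5 + ["Y"] * 5, index=m.sample_ids)
        scores = metsig_score(m, SignatureDefinition("CDC42", ["a", "b"]), groups=groups)
        assert scores["metsig"].iloc[:5].sum() == pytest.approx(0.0, abs=1e-10)
        assert scores["metsig"].iloc[5:].sum() == pytest.approx(0.0, abs=1e-10)


class TestMetSigScorer:
    def test_fit_transform_matches_function(self, rng):
        values = rng.normal(size=(3, 12))
        m = _em(values, genes=["a", "b", "CDC42"])
        sig = SignatureDefinition("CDC42", ["a", "b"])
        est = MetSigScorer(signature=sig).fit(m)
        np.testing.assert_allclose(
            est.transform(m)["metsig"], metsig_score(m, sig)["metsig"], atol=1e-10
        )

    def test_sklearn_param_interface(self):
        est = MetSigScorer()
        assert "signature" in est.get_params()
        est.set_params(signature=SignatureDefinition("CDC42", ["a"]))
        assert est.get_params()["signature"].genes == ["a"]


class TestDeriveSignature:
    def test_tfmap_covering_nothing_annihilates(self):
        mats = []
        for c, s in (("A", 11), ("B", 12)):
            m, _, truth = simulate_bulk_cohort(
                BulkSimSpec(n_samples=30, n_genes=200, tracked_fraction=1.0,
                            cohort=c, seed=s)
            )
            mats.append(m)
        tfmap = {"NFE2L1": {"NOT_A_GENE"}}
        with pytest.warns(UserWarning):
            with pytest.raises(EmptySignatureError):
                derive_signature(mats[0], mats[1], tfmap, {"NFE2L1"}, "CDC42")

    def test_null_cohorts_yield_no_or_tiny_signature(self):
        # label permutation analogue: no planted module at all
        empties = 0
        for seed in range(10):
            mats = []
            for c, s in (("A", seed * 2), ("B", seed * 2 + 1)):
                m, _, truth = simulate_bulk_cohort(
                    BulkSimSpec(n_samples=30, n_genes=500, module_beta=0.0,
                                tracked_fraction=1.0, cohort=c, seed=s)
                )
                mats.append(m)
            tfmap = {"NFE2L1": set(truth.module_gene_ids)
                     | {g for g in mats[0].gene_ids if g.startswith("G")}}
            try:
                sig = derive_signature(mats[0], mats[1], tfmap, {"NFE2L1"}, "CDC42")
                if len(sig) <= 2:
                    empties += 1
            except EmptySignatureError:
                empties += 1
        assert empties >= 9
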