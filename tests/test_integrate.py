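import numpy as np
import pandas as pd
import pytest

import tempoclust as tc
from tempoclust.integrate import linkage_to_newick, subtree_leaf_sets


def complete_linkage_reference(X):
    """Brute-force agglomeration: merge the pair of clusters with the
    smallest maximum pairwise Euclidean distance; return sorted heights."""
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    np.linalg.norm(X[a] - X[b])
                    for a in clusters[i] for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestQuantileNormalize:
    def test_worked_two_column_example(self):
        M = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = tc.quantile_normalize(M)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        M = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(tc.quantile_normalize(M), M)

    def test_columns_share_sorted_values_and_idempotence(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = tc.quantile_normalize(M)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            np.testing.assert_allclose(np.sort(out[c].to_numpy()), ref, atol=1e-12)
        np.testing.assert_allclose(tc.quantile_normalize(out), out, atol=1e-12)

    def test_ties_get_mean_of_tied_reference_values(self):
        M = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = tc.quantile_normalize(M)
        # reference = [1.5, 2.5, 5.5]; the tied pair shares (1.5+2.5)/2
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 5.5])

    def test_single_column_warns_and_returns_unchanged(self):
        M = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = tc.quantile_normalize(M)
        pd.testing.assert_frame_equal(out, M)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            tc.quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


class TestScaleToRange:
    def test_worked_example_hits_both_endpoints(self):
        out = tc.scale_to_range(np.array([-2.0, 0.0, 2.0]))
        np.testing.assert_allclose(out, [-4.03, 0.0, 4.07])

    def test_exact_span_is_fixed_point(self):
        v = np.array([-4.03, -1.0, 0.0, 2.0, 4.07])
        np.testing.assert_allclose(tc.scale_to_range(v), v)

    def test_sign_rank_and_bounds_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = rng.normal(0, rng.uniform(0.1, 5), size=20)
            out = tc.scale_to_range(v)
            assert (np.sign(out) == np.sign(v)).all()
            assert out.min() >= -4.03 - 1e-12 and out.max() <= 4.07 + 1e-12
            np.testing.assert_array_equal(np.argsort(out, kind="stable"),
                                          np.argsort(v, kind="stable"))

    def test_all_zero_returned_unchanged(self):
        np.testing.assert_array_equal(tc.scale_to_range(np.zeros(4)), np.zeros(4))

    def test_target_must_straddle_zero(self):
        with pytest.raises(ValueError):
            tc.scale_to_range(np.array([1.0]), target=(1.0, 2.0))


class TestSelectRecurrent:
    def _studies(self, flags):
        genes = [f"g{i}" for i in range(len(flags[0]))]
        return [
            tc.StudyComparison(
                study_id=f"s{j}",
                ratios=pd.Series(np.zeros(len(genes)), index=genes),
                significant=pd.Series(f, index=genes),
            )
            for j, f in enumerate(flags)
        ]

    def test_at_least_two_of_many(self):
        studies = self._studies([[True, True, False], [True, False, False],
                                 [False, False, False]])
        selected, counts = tc.select_recurrent(studies)
        assert selected == ["g0"]
        assert counts.tolist() == [2, 1, 0]

    def test_min_count_one_is_union(self):
        studies = self._studies([[True, False], [False, True]])
        selected, _ = tc.select_recurrent(studies, min_count=1)
        assert set(selected) == {"g0", "g1"}

    def test_fewer_than_two_studies_rejected(self):
        with pytest.raises(ValueError):
            tc.select_recurrent(self._studies([[True]]))


class TestHclustComplete:
    def test_one_dimensional_worked_case(self):
        M = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        Z, order = tc.hclust_complete(M)
        np.testing.assert_allclose(sorted(Z[:, 2]), [1.0, 10.0])
        assert set(order) == {"a", "b", "c"}

    def test_duplicate_items_merge_at_height_zero(self):
        M = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"))
        Z, _ = tc.hclust_complete(M)
        assert Z[0, 2] == 0.0

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(rng.normal(size=(30, 5)))
        Z, _ = tc.hclust_complete(M)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_agrees_with_bruteforce_on_small_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            X = rng.normal(size=(n, 3))
            Z, _ = tc.hclust_complete(pd.DataFrame(X))
            np.testing.assert_allclose(
                sorted(Z[:, 2]), complete_linkage_reference(X), atol=1e-9
            )

    def test_order_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 3))
        Z1, _ = tc.hclust_complete(pd.DataFrame(X))
        Z2, _ = tc.hclust_complete(pd.DataFrame(X[::-1]))
        np.testing.assert_allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]), atol=1e-12)

    def test_missing_imputed_with_warning(self):
        M = pd.DataFrame([[1.0, np.nan], [1.0, 0.0], [3.0, 3.0]])
        with pytest.warns(UserWarning, match="imputed"):
            Z, _ = tc.hclust_complete(M)
        assert Z[0, 2] == 0.0  # NaN treated as 0 makes first two rows identical

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            tc.hclust_complete(pd.DataFrame([[1.0]]))

    def test_newick_export_is_wellformed(self):
        M = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        Z, _ = tc.hclust_complete(M)
        nwk = linkage_to_newick(Z, list(M.index))
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 2
        for leaf in "abc":
            assert leaf in nwk


class TestBuildHeatmapMatrix:
    def _module_studies(self, noise_sd, seed, n_genes=300, n_module=30):
        genes = [f"g{i:05d}" for i in range(1, n_module + 1)]
        mod = tc.StudyModule(genes=genes, studies=[0, 1, 2, 3, 4], effect=3.0)
        studies, _ = tc.simulate_multistudy(
            20, n_genes, [mod], noise_sd=noise_sd, seed=seed
        )
        return studies, genes

    def test_zero_noise_selects_exactly_the_module(self):
        studies, genes = self._module_studies(0.0, seed=1)
        result = tc.build_heatmap_matrix(studies)
        assert set(result.selected_genes) == set(genes)

    def test_affected_studies_form_one_subtree(self):
        studies, _ = self._module_studies(0.2, seed=2)
        result = tc.build_heatmap_matrix(studies)
        sets = subtree_leaf_sets(result.col_linkage, 20)
        affected = {result.col_labels.index(f"study{s:02d}") for s in range(5)}
        assert affected in sets

    def test_duplicated_studies_are_adjacent_in_leaf_order(self):
        studies, _ = self._module_studies(0.2, seed=3)
        twin = tc.StudyComparison(
            study_id="twin", ratios=studies[0].ratios.copy(),
            significant=studies[0].significant.copy(),
        )
        result = tc.build_heatmap_matrix(studies + [twin])
        order = result.col_order
        assert abs(order.index("study00") - order.index("twin")) == 1

    def test_stage_failures_are_labelled(self):
        studies, _ = self._module_studies(0.0, seed=4)
        with pytest.raises(ValueError, match="integration failed"):
            tc.build_heatmap_matrix(studies, min_count=10)
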