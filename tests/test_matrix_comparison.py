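"""Occurrence set algebra, scaling, PCA/HCA and inter-matrix regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psdrisk import matrix_comparison as mcmp
from conftest import frame


class TestOccurrenceSets:
    def test_water_only_compound(self):
        rows = [("a", "water", "2021-07", 1, 5.0, "quantified")]
        occ = mcmp.occurrence_sets(frame(rows))
        assert occ["water"].quantified == {"a"}
        assert "biota" not in occ and "psd_any" not in occ

    def test_detected_includes_below_loq(self):
        rows = [
            ("a", "water", "2021-07", 1, 5.0, "quantified"),
            ("b", "water", "2021-07", 1, None, "detected_below_loq"),
            ("c", "water", "2021-07", 1, None, "not_detected"),
        ]
        occ = mcmp.occurrence_sets(frame(rows))
        assert occ["water"].detected == {"a", "b"}
        assert occ["water"].quantified == {"a"}

    def test_psd_any_is_sorbent_union(self):
        rows = [
            ("a", "psd_hlb", "2021-07", 1, 1.0, "quantified"),
            ("b", "psd_anion", "2021-07", 1, 1.0, "quantified"),
            ("c", "psd_cation", "2021-07", 1, None, "detected_below_loq"),
        ]
        occ = mcmp.occurrence_sets(frame(rows))
        assert occ["psd_any"].detected == {"a", "b", "c"}
        assert occ["psd_any"].quantified == {"a", "b"}

    def test_empty_input(self):
        assert mcmp.occurrence_sets(frame([])) == {}

    def test_quantified_subset_of_detected_everywhere(self, tiny_campaign):
        df, _ = tiny_campaign
        for sets in mcmp.occurrence_sets(df).values():
            assert sets.quantified <= sets.detected


def brute_force_regions(a, b, c):
    """Element-by-element enumeration oracle for three-set Venn regions."""
    regions = {}
    for el in a | b | c:
        key = (el in a, el in b, el in c)
        regions[key] = regions.get(key, 0) + 1
    return regions


class TestVennCounts:
    def test_small_example_against_enumeration(self):
        a, b, c = {1, 2}, {2, 3}, {2}
        counts = mcmp.venn_counts({"A": a, "B": b, "C": c})
        assert counts[("A", "B", "C")] == 1
        assert counts[("A",)] == 1 and counts[("B",)] == 1 and counts[("C",)] == 0
        assert counts[("A", "B")] == 0
        assert sum(counts.values()) == len(a | b | c) == 3

    def test_identical_sets_concentrate_in_center(self):
        s = {1, 2, 3}
        counts = mcmp.venn_counts({"A": set(s), "B": set(s), "C": set(s)})
        assert counts[("A", "B", "C")] == 3
        assert sum(counts.values()) == 3

    def test_disjoint_sets(self):
        counts = mcmp.venn_counts({"A": {1}, "B": {2}, "C": {3}})
        assert counts[("A",)] == counts[("B",)] == counts[("C",)] == 1
        assert sum(v for k, v in counts.items() if len(k) > 1) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 15)),
        b=st.sets(st.integers(0, 15)),
        c=st.sets(st.integers(0, 15)),
    )
    def test_matches_brute_force_on_random_sets(self, a, b, c):
        counts = mcmp.venn_counts({"A": a, "B": b, "C": c})
        oracle = brute_force_regions(a, b, c)
        key_of = {("A",): (True, False, False), ("B",): (False, True, False),
                  ("C",): (False, False, True), ("A", "B"): (True, True, False),
                  ("A", "C"): (True, False, True), ("B", "C"): (False, True, True),
                  ("A", "B", "C"): (True, True, True)}
        for region, mask in key_of.items():
            assert counts[region] == oracle.get(mask, 0)
        assert sum(counts.values()) == len(a | b | c)


class TestMinMaxScale:
    def test_affine_row(self):
        df = pd.DataFrame([[2.0, 4.0, 6.0]])
        assert mcmp.minmax_scale(df).iloc[0].tolist() == [0.0, 0.5, 1.0]

    def test_constant_row_maps_to_zero(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0]])
        assert mcmp.minmax_scale(df).iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_missing_entries_zero_filled_before_scaling(self):
        df = pd.DataFrame([[np.nan, 4.0, 8.0]])
        assert mcmp.minmax_scale(df).iloc[0].tolist() == [0.0, 0.5, 1.0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            mcmp.minmax_scale(pd.DataFrame())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(-100, 100), min_size=3, max_size=6),
            min_size=1,
            max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_rows_span_unit_interval_and_idempotent(self, rows):
        df = pd.DataFrame(rows)
        scaled = mcmp.minmax_scale(df)
        for _, row in scaled.iterrows():
            assert row.min() >= 0.0 and row.max() <= 1.0
            if row.nunique() > 1:
                assert row.min() == 0.0 and row.max() == pytest.approx(1.0)
        pd.testing.assert_frame_equal(mcmp.minmax_scale(scaled), scaled)


class TestPca:
    def test_rank_one_data_loads_on_first_component(self):
        x = np.linspace(0, 1, 8)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        res = mcmp.pca(df, n_components=2)
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.random((5, 4)), columns=list("abcd"))
        res = mcmp.pca(df, n_components=4)
        X = df.to_numpy() - df.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        oracle_scores = X @ evecs
        for j in range(res.scores.shape[1]):
            got = res.scores.iloc[:, j].to_numpy()
            want = oracle_scores[:, j]
            # orientation-insensitive comparison; magnitudes must agree
            assert np.allclose(np.abs(got), np.abs(want), atol=1e-10)
        total_var = np.trace(np.cov(X, rowvar=False))
        assert np.allclose(
            res.explained_variance_pct[: len(evals)],
            100 * evals / total_var,
            atol=1e-8,
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((6, 5)))
        res = mcmp.pca(df, n_components=3)
        for col in res.loadings.columns:
            loadings = res.loadings[col]
            assert loadings.loc[loadings.abs().idxmax()] > 0

    def test_variance_accounting_and_orthogonality(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.random((10, 4)))
        res = mcmp.pca(df, n_components=4)
        assert res.explained_variance_pct.sum() == pytest.approx(100.0)
        assert (np.diff(res.explained_variance_pct) <= 1e-9).all()
        cov = np.cov(res.scores.to_numpy(), rowvar=False)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-10)

    def test_top_compounds_reported(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((6, 12)))
        res = mcmp.pca(df, n_components=2, top_k=10)
        assert len(res.top_compounds) == 10


class TestHca:
    def test_two_separated_groups_recovered(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [5.0, 5.0], [5.1, 5.0], [5.0, 5.1]]
        )
        res = mcmp.hierarchical_clustering(df, n_clusters=2)
        labels = res.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert res.co_clustered(0, 1) and not res.co_clustered(0, 3)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((6, 4)))
        res = mcmp.hierarchical_clustering(df)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_row_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.random((7, 4)))
        perm = rng.permutation(7)
        res1 = mcmp.hierarchical_clustering(df)
        res2 = mcmp.hierarchical_clustering(df.iloc[perm].reset_index(drop=True))
        # same multiset of merge heights => isomorphic dendrograms here
        assert np.allclose(np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2]))
        inv = np.argsort(perm)
        for i in range(7):
            for j in range(i + 1, 7):
                assert res1.co_clustered(i, j) == res2.co_clustered(inv[i], inv[j])

    def test_single_row_trivial_tree(self):
        res = mcmp.hierarchical_clustering(pd.DataFrame([[1.0, 2.0]]))
        assert res.linkage.shape == (0, 4) and list(res.labels) == [1]


class TestLinearCorrelation:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = mcmp.linear_matrix_correlation(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_value < 1e-6

    def test_null_noise_is_not_significant(self):
        rng = np.random.default_rng(123)
        x, y = rng.normal(size=50), rng.normal(size=50)
        fit = mcmp.linear_matrix_correlation(x, y)
        assert fit.r2 < 0.2 and fit.p_value > 0.05

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.random(20)
        y = 1.5 * x + rng.normal(0, 0.2, 20)
        fit = mcmp.linear_matrix_correlation(x, y)
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            mcmp.linear_matrix_correlation([1.0, 2.0], [1.0, 2.0])

    def test_pairing_by_compound_month(self, tiny_campaign):
        df, _ = tiny_campaign
        paired = mcmp.pair_concentrations(df, "water", "biota")
        # imidacloprid has quantified water+biota in both months; citalopram none
        assert set(paired["compound_id"]) == {"imidacloprid"}
        assert len(paired) == 2
        july = paired[paired.month == "2021-07"].iloc[0]
        assert july["water"] == pytest.approx(66.0)  # mean of 60, 72
        assert july["biota"] == pytest.approx(63.0)
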