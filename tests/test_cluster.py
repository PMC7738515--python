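"""Distances, average-linkage clustering and PCA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossrppa.cluster import (
    distance_matrix,
    hierarchical_cluster,
    pca,
    two_dimensional_cluster,
)
from crossrppa.exceptions import SchemaError

from . import oracles

METRICS = ["spearman", "euclidean", "kendall"]


def frame(X):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X, index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"c{j}" for j in range(X.shape[1])],
    )


class TestDistances:
    @pytest.mark.parametrize("metric", METRICS)
    def test_identical_columns_have_zero_distance(self, metric, rng):
        x = rng.normal(size=6)
        dm = distance_matrix(frame(np.column_stack([x, x, rng.normal(size=6)])),
                             metric=metric)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_give_spearman_distance_two(self):
        m = frame(np.column_stack([np.arange(6.0), np.arange(6.0)[::-1]]))
        dm = distance_matrix(m, metric="spearman")
        assert dm.d[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("metric", METRICS)
    def test_random_matrix_matches_first_principles_oracle(self, metric, rng):
        X = rng.normal(size=(6, 5))
        dm = distance_matrix(frame(X), metric=metric)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = oracles.distance(X[:, i].tolist(), X[:, j].tolist(), metric)
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("metric", METRICS)
    def test_metric_axioms_on_random_inputs(self, metric, rng):
        for _ in range(10):
            X = rng.normal(size=(7, 5))
            # ties exercise the tie-corrected variants
            X[rng.integers(0, 7), :] = X[0, :]
            d = distance_matrix(frame(X), metric=metric).d
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert (d >= 0).all()
            if metric != "euclidean":
                assert (d <= 2 + 1e-12).all()

    def test_spearman_invariant_under_monotone_transform(self, rng):
        X = rng.normal(size=(8, 4))
        d1 = distance_matrix(frame(X), metric="spearman").d
        X2 = X.copy()
        X2[:, 2] = np.exp(X2[:, 2])  # strictly increasing transform
        d2 = distance_matrix(frame(X2), metric="spearman").d
        assert np.allclose(d1, d2, atol=1e-12)

    def test_pairwise_complete_pair_below_minimum_is_missing(self):
        X = np.array(
            [[1, 1.0], [2, np.nan], [3, np.nan], [4, np.nan], [5, 2.0]]
        )
        dm = distance_matrix(frame(X), metric="spearman", min_complete=3)
        assert np.isnan(dm.d[0, 1])
        with pytest.raises(SchemaError):
            hierarchical_cluster(dm)


class TestHierarchical:
    def test_duplicate_items_merge_first_at_zero_height(self, rng):
        x = rng.normal(size=6)
        X = np.column_stack([x, rng.normal(size=6), x, rng.normal(size=6)])
        dend = hierarchical_cluster(distance_matrix(frame(X), metric="spearman"))
        node, left, right, h = dend.merges[0]
        assert (left, right) == (0, 2)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_single_item_has_no_merges(self):
        from crossrppa.cluster import DistanceMatrix

        dend = hierarchical_cluster(DistanceMatrix(["a"], np.zeros((1, 1)), "spearman"))
        assert dend.merges == []
        assert dend.leaf_order == ["a"]

    @pytest.mark.parametrize("metric", METRICS)
    def test_merge_sequence_matches_bruteforce_oracle(self, metric, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            X = rng.normal(size=(6, n))
            dm = distance_matrix(frame(X), metric=metric)
            dend = hierarchical_cluster(dm)
            expected = oracles.average_linkage(dm.d)
            assert len(dend.merges) == len(expected)
            for got, exp in zip(dend.merges, expected):
                assert got[:3] == exp[:3]
                assert got[3] == pytest.approx(exp[3], abs=1e-9)

    def test_leaf_order_is_permutation_of_labels(self, rng):
        X = rng.normal(size=(6, 7))
        dend = hierarchical_cluster(distance_matrix(frame(X), metric="euclidean"))
        assert sorted(dend.leaf_order) == sorted(dend.labels)

    def test_cophenetic_matrix_is_ultrametric_like(self, rng):
        X = rng.normal(size=(6, 5))
        dend = hierarchical_cluster(distance_matrix(frame(X), metric="euclidean"))
        C = dend.cophenetic_matrix()
        assert np.allclose(C, C.T)
        assert (np.diag(C) == 0).all()


class TestTwoDimensional:
    def test_block_structure_yields_contiguous_groups(self, rng):
        base1 = rng.normal(size=8)
        base2 = rng.normal(size=8)
        cols = [base1 + rng.normal(0, 0.05, 8) for _ in range(3)]
        cols += [base2 + rng.normal(0, 0.05, 8) for _ in range(3)]
        m = frame(np.column_stack(cols))
        _, col_dend, _ = two_dimensional_cluster(m, metric="euclidean")
        order = [int(l[1:]) for l in col_dend.leaf_order]
        groups = ["".join("AB"[i >= 3] for i in order)]
        assert groups[0] in ("AAABBB", "BBBAAA")

    def test_transposing_swaps_dendrograms(self, rng):
        X = rng.normal(size=(5, 4))
        m = pd.DataFrame(X, index=[f"r{i}" for i in range(5)],
                         columns=[f"c{j}" for j in range(4)])
        rd, cd, _ = two_dimensional_cluster(m, metric="euclidean")
        rd_t, cd_t, _ = two_dimensional_cluster(m.T, metric="euclidean")
        assert rd.merges == cd_t.merges and cd.merges == rd_t.merges

    def test_reordered_matrix_preserves_values(self, rng):
        m = frame(rng.normal(size=(6, 5)))
        _, _, reordered = two_dimensional_cluster(m, metric="spearman")
        assert sorted(reordered.to_numpy().ravel()) == pytest.approx(
            sorted(m.to_numpy().ravel())
        )


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=4)
        res = pca(frame(np.outer(u, v)), n_components=1)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_full_reconstruction_matches_centred_input(self, rng):
        m = frame(rng.normal(size=(6, 4)))
        res = pca(m)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centred = m.to_numpy() - m.to_numpy().mean(axis=0)
        assert np.allclose(recon, centred, atol=1e-9)

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(6, 4))
        res = pca(frame(X))
        centred = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(centred.T)))[::-1]
        sample_var = (res.scores.to_numpy() ** 2).sum(axis=0) / (X.shape[0] - 1)
        assert np.allclose(sample_var, eig[: len(sample_var)], atol=1e-9)

    def test_scores_are_uncorrelated(self, rng):
        res = pca(frame(rng.normal(size=(10, 5))))
        cov = np.cov(res.scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_components_beyond_rank_truncated_with_warning(self, rng):
        u = rng.normal(size=5)
        v = rng.normal(size=4)
        with pytest.warns(UserWarning, match="rank"):
            res = pca(frame(np.outer(u, v)), n_components=4)
        assert res.scores.shape[1] == 1

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(7, 4))
        r1, r2 = pca(frame(X)), pca(frame(X.copy()))
        assert np.allclose(r1.loadings.to_numpy(), r2.loadings.to_numpy())
        for c in r1.loadings.columns:
            load = r1.loadings[c]
            assert load.iloc[int(np.argmax(np.abs(load.to_numpy())))] > 0
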