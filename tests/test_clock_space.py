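"""PCA clock space, sBSDmin/MDS legacy pathway, PAM + gap clustering."""

import numpy as np
import pandas as pd
import pytest

from clockspace import (
    TreeError,
    annotate_space,
    group_clocks,
    mds_embed,
    parse_newick,
    pca_clock_space,
    prepare_matrix,
    sbsd_min,
)
from clockspace.clock_space import filter_extreme_loci, pam


def prepared_from(array, **kwargs):
    kwargs.setdefault("log_transform", False)
    return prepare_matrix(pd.DataFrame(np.asarray(array, dtype=float)), **kwargs)


class TestPrepareMatrix:
    def test_complete_matrix_is_column_standardized(self, rng):
        X = rng.normal(2.0, 3.0, size=(50, 5))
        prep = prepared_from(X)
        data = prep.data.to_numpy()
        assert np.allclose(data.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(data.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_column_beyond_missing_threshold_is_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        X.loc[X.index[:6], "c"] = np.nan  # 60% missing
        prep = prepare_matrix(X, log_transform=False, max_missing_col=0.5)
        assert "c" not in prep.data.columns
        assert prep.transform_log["dropped_columns"] == ["c"]

    def test_imputed_value_equals_observed_column_mean(self):
        X = pd.DataFrame(
            [
                [1.0, 5.0, 1.0],
                [2.0, 6.0, 2.0],
                [np.nan, 7.0, 3.0],
                [4.0, 8.0, 2.5],
                [5.0, 9.0, 1.5],
            ],
            columns=list("xyz"),
        )
        prep = prepare_matrix(X, log_transform=False)
        observed_mean = np.mean([1.0, 2.0, 4.0, 5.0])
        # back out the imputed raw value from the standardized cell
        col = np.array([1.0, 2.0, observed_mean, 4.0, 5.0])
        expected = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(prep.data["x"].to_numpy(), expected)
        assert prep.transform_log["n_imputed"] == 1

    def test_log_transform_maps_zeros_to_missing_then_imputes(self):
        X = pd.DataFrame(np.full((6, 3), 2.0), columns=list("abc"))
        X.iloc[0, 0] = 0.0
        X.iloc[1:, 0] = [1, 2, 3, 4, 5]
        X["b"] = [1, 2, 3, 4, 5, 6]
        X["c"] = [6, 5, 4, 3, 2, 1]
        prep = prepare_matrix(X, log_transform=True)
        assert prep.transform_log["n_imputed"] == 1

    def test_too_small_matrix_is_an_error(self, rng):
        with pytest.raises(ValueError):
            prepared_from(rng.normal(size=(2, 5)))


class TestPCA:
    def test_perfectly_correlated_columns(self, rng):
        z = rng.normal(size=40)
        X = np.column_stack([z] * 5)
        space = pca_clock_space(prepared_from(X))
        assert space.eigenvalues[0] == pytest.approx(5.0, abs=1e-8)
        assert space.variance_proportions[0] == pytest.approx(1.0)

    def test_iid_columns_have_near_unit_eigenvalues(self, rng):
        X = rng.normal(size=(5000, 10))
        space = pca_clock_space(prepared_from(X))
        assert space.eigenvalues.min() > 0.8
        assert space.eigenvalues.max() < 1.2

    def test_eigenvalues_match_independent_solver_on_fixture(self):
        # independent oracle: general (non-symmetric) eigensolver applied to
        # the correlation matrix computed by numpy.corrcoef
        X = np.array(
            [
                [3, 7, 1, 4],
                [5, 2, 8, 6],
                [9, 4, 2, 1],
                [2, 8, 5, 3],
                [7, 1, 9, 8],
                [4, 6, 3, 2],
            ],
            dtype=float,
        )
        space = pca_clock_space(prepared_from(X))
        oracle = np.sort(np.real(np.linalg.eig(np.corrcoef(X.T))[0]))[::-1]
        assert np.allclose(space.eigenvalues, oracle, atol=1e-8)

    def test_eigenvalues_sum_to_p_prime(self, rng):
        X = rng.normal(size=(30, 8))
        space = pca_clock_space(prepared_from(X))
        assert space.eigenvalues.sum() == pytest.approx(8.0, abs=1e-8)
        assert space.variance_proportions.sum() == pytest.approx(1.0)

    def test_loadings_are_orthonormal(self, rng):
        X = rng.normal(size=(30, 6))
        L = pca_clock_space(prepared_from(X)).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-8)

    def test_scores_times_loadings_reconstruct_matrix(self, rng):
        X = rng.normal(size=(25, 6))
        prep = prepared_from(X)
        space = pca_clock_space(prep)
        recon = space.scores.to_numpy() @ space.loadings.to_numpy().T
        assert np.allclose(recon, prep.data.to_numpy(), atol=1e-6)

    def test_locus_permutation_permutes_scores_only(self, rng):
        X = rng.normal(size=(20, 5))
        perm = rng.permutation(20)
        s1 = pca_clock_space(prepared_from(X))
        s2 = pca_clock_space(prepared_from(X[perm]))
        assert np.allclose(s1.eigenvalues, s2.eigenvalues, atol=1e-10)
        assert np.allclose(
            s1.scores.to_numpy()[perm], s2.scores.to_numpy(), atol=1e-8
        )


class TestSbsdMin:
    def test_identical_trees(self, caterpillar5):
        assert sbsd_min(caterpillar5, caterpillar5) == pytest.approx(0.0)

    def test_scalar_multiple_absorbed(self, caterpillar5):
        scaled = caterpillar5.clone(depth=1)
        for node in scaled.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= 2.7
        assert sbsd_min(caterpillar5, scaled) == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        a = parse_newick("((A:1,B:2):0.5,(C:3,D:0.7):0.5);")
        b = parse_newick("((A:2,B:1):0.4,(C:1,D:2.2):0.6);")
        observed = sbsd_min(a, b)
        # brute-force oracle on hand-enumerated matched branch vectors:
        # pendants A,B,C,D plus the merged root split {A,B}|{C,D}
        va = np.array([1, 2, 3, 0.7, 1.0])
        vb = np.array([2, 1, 1, 2.2, 1.0])
        grid = np.linspace(1e-3, 10, 200001)

        def directed(u, v):
            return min(
                np.linalg.norm(u - s * v) for s in grid
            ) / np.linalg.norm(u)

        expected = min(directed(va, vb), directed(vb, va))
        assert observed == pytest.approx(expected, abs=1e-6)

    def test_symmetry(self, caterpillar5):
        other = parse_newick("((((A:2,B:1):1,C:4):1,D:1):1,E:2);")
        assert sbsd_min(caterpillar5, other) == pytest.approx(
            sbsd_min(other, caterpillar5)
        )

    def test_too_few_shared_taxa_is_an_error(self, caterpillar5):
        small = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError):
            sbsd_min(caterpillar5, small)


class TestMDS:
    def test_zero_distances_embed_at_origin(self):
        coords = mds_embed(np.zeros((4, 4)))
        assert np.allclose(coords, 0)

    def test_collinear_points(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords = mds_embed(D)
        embedded = np.linalg.norm(
            coords[:, None, :] - coords[None, :, :], axis=-1
        )
        assert np.allclose(embedded, D, atol=1e-6)

    def test_recovers_euclidean_point_cloud(self, rng):
        pts = rng.normal(size=(30, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = mds_embed(D)
        embedded = np.linalg.norm(
            coords[:, None] - coords[None, :], axis=-1
        )
        assert np.sqrt(np.mean((embedded - D) ** 2)) < 1e-6

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            mds_embed(D)


class TestGroupClocks:
    def test_two_separated_blobs(self, rng):
        X = np.vstack(
            [
                rng.normal(0.0, 1.0, size=(50, 2)),
                rng.normal(20.0, 1.0, size=(50, 2)),
            ]
        )
        res = group_clocks(X, k_max=6, B=30, seed=4)
        assert res.k_selected == 2
        labels = res.assignments.to_numpy()
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_single_blob_selects_one_cluster(self, rng):
        X = rng.normal(size=(100, 2))
        res = group_clocks(X, k_max=6, B=30, seed=4)
        assert res.k_selected == 1

    def test_k1_contains_all_points(self, rng):
        X = rng.normal(size=(20, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        medoids, assignments = pam(D, 1)
        assert len(medoids) == 1
        assert len(set(assignments)) == 1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 2))
        r1 = group_clocks(X, k_max=4, B=20, seed=9)
        r2 = group_clocks(X, k_max=4, B=20, seed=9)
        assert r1.k_selected == r2.k_selected
        assert (r1.assignments == r2.assignments).all()
        assert np.allclose(r1.gap_curve.gap, r2.gap_curve.gap)


class TestAnnotateSpace:
    def _space(self, rng, n=12):
        X = rng.normal(size=(n, 4))
        return pca_clock_space(prepared_from(X))

    def test_minimal_table_has_coordinates(self, rng):
        table = annotate_space(self._space(rng))
        assert list(table.columns) == ["PC1", "PC2"]
        assert len(table) == 12

    def test_user_column_with_partial_coverage(self, rng):
        space = self._space(rng)
        user = pd.DataFrame(
            {"coding": [1] * 6}, index=space.scores.index[:6]
        )
        table = annotate_space(space, user_table=user)
        assert table["coding"].notna().sum() == 6
        assert table["coding"].isna().sum() == 6

    def test_duplicate_user_ids_rejected(self, rng):
        space = self._space(rng)
        user = pd.DataFrame({"x": [1, 2]}, index=["a", "a"])
        with pytest.raises(ValueError):
            annotate_space(space, user_table=user)

    def test_mean_branch_support(self):
        from clockspace.clock_space import mean_branch_support

        t = parse_newick("((A:1,B:1)90:1,(C:1,D:1)100:1);")
        assert mean_branch_support(t) == pytest.approx(95.0)

    def test_extreme_locus_filter_keeps_central_loci(self, rng):
        space = self._space(rng, n=50)
        kept = filter_extreme_loci(space, quantile=0.8)
        assert 0 < len(kept) < 50
        for pc in ("PC1", "PC2"):
            cutoff = space.scores[pc].abs().quantile(0.8)
            assert (space.scores.loc[kept, pc].abs() <= cutoff + 1e-12).all()
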