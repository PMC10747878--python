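"""Graph construction: Pearson node features, partial-correlation edge
weights, upper-triangle vectorization, and masking semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectofuse.graphs import (
    build_graph,
    edge_index_map,
    partial_correlation_matrix,
    pearson_matrix,
    unvectorize_upper,
    vectorize_upper,
)
from connectofuse.selection import FeatureMask


def pearson_oracle(ts):
    """Brute-force double-loop Pearson correlation."""
    t, r = ts.shape
    out = np.ones((r, r))
    for i in range(r):
        for j in range(r):
            x, y = ts[:, i] - ts[:, i].mean(), ts[:, j] - ts[:, j].mean()
            out[i, j] = (x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum())
    return out


def partial_corr_oracle(ts):
    """Regression-residual partial correlation: residualize each pair of
    columns on all the others (with intercept) and correlate the residuals."""
    t, r = ts.shape
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            others = [k for k in range(r) if k not in (i, j)]
            design = np.column_stack([np.ones(t), ts[:, others]])
            ri = ts[:, i] - design @ np.linalg.lstsq(design, ts[:, i], rcond=None)[0]
            rj = ts[:, j] - design @ np.linalg.lstsq(design, ts[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestPearson:
    @pytest.mark.parametrize(
        "y, expected",
        [((2, 4, 6), 1.0), ((3, 2, 1), -1.0), ((1, 3, 2), 0.5)],
    )
    def test_hand_worked_pairs(self, y, expected):
        ts = np.column_stack([(1.0, 2.0, 3.0), y])
        assert pearson_matrix(ts)[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            ts = rng.standard_normal((5, 4))
            np.testing.assert_allclose(pearson_matrix(ts), pearson_oracle(ts), atol=1e-12)

    def test_constant_column_error_names_roi(self, rng):
        ts = rng.standard_normal((10, 3))
        ts[:, 1] = 2.5
        with pytest.raises(ValueError, match=r"\[1\]"):
            pearson_matrix(ts)

    def test_permissive_mode_zero_fills(self, rng):
        ts = rng.standard_normal((10, 3))
        ts[:, 1] = 2.5
        r = pearson_matrix(ts, permissive=True)
        assert r[0, 1] == 0.0 and r[1, 2] == 0.0 and r[1, 1] == 1.0

    def test_permutation_equivariance(self, rng):
        ts = rng.standard_normal((30, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            pearson_matrix(ts[:, perm]), pearson_matrix(ts)[np.ix_(perm, perm)], atol=1e-12
        )


class TestPartialCorrelation:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((5000, 5))
        rho = partial_correlation_matrix(ts, shrinkage=0.0)
        off = rho[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_closed_form_from_constructed_precision(self):
        # target precision [[2,-1],[-1,2]] -> rho_12 = -(-1)/sqrt(4) = 0.5;
        # build a sample whose empirical covariance is exactly inv(theta)
        theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
        sigma = np.linalg.inv(theta)
        rng = np.random.default_rng(1)
        z = rng.standard_normal((200, 2))
        z -= z.mean(axis=0)
        s = z.T @ z / 200
        z = z @ np.linalg.inv(np.linalg.cholesky(s)).T @ np.linalg.cholesky(sigma).T
        rho = partial_correlation_matrix(z, shrinkage=0.0)
        assert rho[0, 1] == pytest.approx(0.5, abs=1e-8)

    def test_matches_regression_residual_oracle(self, rng):
        ts = rng.standard_normal((80, 5))
        rho = partial_correlation_matrix(ts, shrinkage=0.0)
        np.testing.assert_allclose(rho, partial_corr_oracle(ts), atol=1e-8)

    def test_symmetry_and_unit_diagonal(self, rng):
        ts = rng.standard_normal((40, 6))
        rho = partial_correlation_matrix(ts, shrinkage=0.2)
        np.testing.assert_array_equal(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_singular_covariance_instructs_shrinkage(self, rng):
        ts = rng.standard_normal((5, 10))  # T < R -> singular sample covariance
        with pytest.raises(ValueError, match="shrinkage"):
            partial_correlation_matrix(ts, shrinkage=0.0)

    def test_auto_shrinkage_handles_t_less_than_r(self, rng):
        ts = rng.standard_normal((15, 30))
        rho = partial_correlation_matrix(ts, shrinkage="auto")
        assert np.isfinite(rho).all()

    def test_permutation_equivariance(self, rng):
        ts = rng.standard_normal((60, 6))
        perm = rng.permutation(6)
        a = partial_correlation_matrix(ts[:, perm], shrinkage=0.1)
        b = partial_correlation_matrix(ts, shrinkage=0.1)[np.ix_(perm, perm)]
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestVectorize:
    def test_connectome_dimension_for_200_regions(self):
        m = np.eye(200)
        assert vectorize_upper(m).shape == (19900,)

    @pytest.mark.parametrize("r, expected_len", [(2, 1), (3, 3), (5, 10)])
    def test_lengths(self, r, expected_len):
        assert vectorize_upper(np.eye(r)).shape == (expected_len,)

    def test_two_by_two_value(self):
        assert vectorize_upper(np.array([[1.0, 0.4], [0.4, 1.0]])) == pytest.approx([0.4])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_identity(self, r, seed):
        vals = np.random.default_rng(seed).uniform(-1, 1, size=r * (r - 1) // 2)
        m = unvectorize_upper(vals, r)
        np.testing.assert_array_equal(vectorize_upper(m), vals)
        np.testing.assert_array_equal(unvectorize_upper(vectorize_upper(m), r), m)

    def test_index_map_bijective(self):
        pairs = edge_index_map(7)
        assert len(pairs) == 21
        assert len({tuple(p) for p in pairs}) == 21
        assert all(i < j for i, j in pairs)


class TestBuildGraph:
    def test_complete_graph_default(self, rng):
        ts = rng.standard_normal((50, 5))
        g = build_graph(pearson_matrix(ts), partial_correlation_matrix(ts, 0.1))
        assert g.n_nodes == 5
        assert len(g.edges) == 10
        assert g.node_features.shape == (5, 5)
        assert ((g.edge_weights >= 0) & (g.edge_weights <= 1)).all()

    def test_edge_weight_is_absolute_partial(self):
        pearson = np.eye(3)
        partial = np.eye(3)
        partial[1, 2] = partial[2, 1] = -0.3
        g = build_graph(pearson, partial)
        idx = [k for k, (i, j) in enumerate(g.edges) if (i, j) == (1, 2)][0]
        assert g.edge_weights[idx] == pytest.approx(0.3)

    def test_empty_mask_gives_identity_node_features(self, rng):
        ts = rng.standard_normal((50, 4))
        mask = FeatureMask(retained=np.array([], dtype=int), ranking=np.arange(1, 7), n_original=6)
        g = build_graph(pearson_matrix(ts), partial_correlation_matrix(ts, 0.1), mask=mask)
        np.testing.assert_array_equal(g.node_features, np.eye(4))

    def test_mask_for_wrong_size_rejected(self, rng):
        ts = rng.standard_normal((50, 4))
        mask = FeatureMask(retained=np.array([0]), ranking=np.arange(1, 11), n_original=10)
        with pytest.raises(ValueError, match="different number of ROIs"):
            build_graph(pearson_matrix(ts), partial_correlation_matrix(ts, 0.1), mask=mask)

    def test_top_k_rule_sparsifies(self, rng):
        ts = rng.standard_normal((100, 10))
        g = build_graph(
            pearson_matrix(ts), partial_correlation_matrix(ts, 0.1), edge_rule="top_k", top_k=2
        )
        assert 0 < len(g.edges) < 45
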