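"""Deterministic PLS correlation core: z-scoring, SVD, scores, loadings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plscog import generate_latent_dataset, random_ground_truth
from plscog.pls import (
    PLSCorrelation,
    column_score_correlations,
    covariance_explained,
    cross_block,
    decompose,
    zscore_columns,
)


class TestZscore:
    def test_simple_column(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized(self, rng):
        x = zscore_columns(rng.standard_normal((26, 14)))
        assert np.allclose(zscore_columns(x), x, atol=1e-10)
        assert np.abs(x.mean(axis=0)).max() < 1e-10
        assert np.abs(x.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_columns(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))


class TestCrossBlock:
    def test_entries_are_pearson_r(self, rng):
        x = rng.standard_normal((5, 2))
        y = rng.standard_normal((5, 2))
        r = cross_block(zscore_columns(x), zscore_columns(y))
        for i in range(2):
            for j in range(2):
                assert r[i, j] == pytest.approx(np.corrcoef(x[:, i], y[:, j])[0, 1],
                                                abs=1e-12)

    def test_identical_column_gives_one(self, rng):
        x = rng.standard_normal((10, 1))
        r = cross_block(zscore_columns(x), zscore_columns(x.copy()))
        assert r[0, 0] == pytest.approx(1.0)

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="subject"):
            cross_block(rng.standard_normal((5, 2)), rng.standard_normal((6, 2)))


class TestDecompose:
    def test_diagonal_matrix(self):
        s, u, v = decompose(np.diag([3.0, 4.0]))
        assert np.allclose(s, [4.0, 3.0])

    def test_rank_one_recovery(self, rng):
        uvec = rng.standard_normal(20)
        uvec /= np.linalg.norm(uvec)
        vvec = rng.standard_normal(6)
        vvec /= np.linalg.norm(vvec)
        s, u, v = decompose(2.5 * np.outer(uvec, vvec))
        assert s[0] == pytest.approx(2.5)
        assert np.allclose(s[1:], 0, atol=1e-10)
        assert abs(float(u[:, 0] @ uvec)) == pytest.approx(1.0)
        assert abs(float(v[:, 0] @ vvec)) == pytest.approx(1.0)

    def test_sign_convention_anchors_largest_v_element(self, rng):
        r = rng.standard_normal((12, 5))
        _, _, v = decompose(r)
        for k in range(v.shape[1]):
            assert v[np.argmax(np.abs(v[:, k])), k] > 0

    def test_reconstruction_and_orthonormality(self, rng):
        r = rng.standard_normal((30, 7))
        s, u, v = decompose(r)
        assert np.linalg.norm(u @ np.diag(s) @ v.T - r) / np.linalg.norm(r) < 1e-8
        assert np.allclose(u.T @ u, np.eye(7), atol=1e-8)
        assert np.allclose(v.T @ v, np.eye(7), atol=1e-8)

    def test_eigendecomposition_oracle(self, rng):
        """Singular values squared equal the eigenvalues of R'R (independent solver)."""
        r = rng.standard_normal((20, 5))
        s, u, v = decompose(r)
        eigvals = np.sort(np.linalg.eigvalsh(r.T @ r))[::-1]
        assert np.allclose(s**2, eigvals, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            decompose(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestCovarianceExplained:
    def test_two_values(self):
        assert np.allclose(covariance_explained([4.0, 3.0]), [16 / 25, 9 / 25])

    def test_single_lv_is_total(self):
        assert covariance_explained([7.0]) == pytest.approx([1.0])

    def test_sums_to_one(self, rng):
        s = np.sort(np.abs(rng.standard_normal(9)))[::-1]
        assert covariance_explained(s).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            covariance_explained([0.0, 0.0])


class TestModelFit:
    def test_noiseless_rank_one_scores_correlate_perfectly(self, rng):
        z = rng.standard_normal(30)
        uvec = rng.standard_normal(10)
        uvec /= np.linalg.norm(uvec)
        vvec = rng.standard_normal(5)
        vvec /= np.linalg.norm(vvec)
        res = PLSCorrelation(np.outer(z, uvec), np.outer(z, vvec)).fit()
        r = np.corrcoef(res.brain_scores[:, 0], res.behavior_scores[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_score_correlation_nonnegative_under_convention(self, rng):
        for seed in range(5):
            g = np.random.default_rng(seed)
            res = PLSCorrelation(g.standard_normal((20, 8)),
                                 g.standard_normal((20, 4))).fit()
            for k in range(res.n_lv):
                r = np.corrcoef(res.brain_scores[:, k], res.behavior_scores[:, k])[0, 1]
                assert r >= -1e-12

    def test_flipping_salience_flips_scores(self, rng):
        x = rng.standard_normal((15, 6))
        res = PLSCorrelation(x, rng.standard_normal((15, 3))).fit()
        u_flipped = res.brain_saliences.copy()
        u_flipped[:, 0] *= -1
        lx = zscore_columns(x) @ u_flipped
        assert np.allclose(lx[:, 0], -res.brain_scores[:, 0])

    def test_planted_effect_scores_track_each_other(self):
        truth = random_ground_truth(100, 10, 8, effect=5.0, seed=7)
        d = generate_latent_dataset(truth)
        res = PLSCorrelation(d.edges, d.cognition).fit()
        r = np.corrcoef(res.brain_scores[:, 0], res.behavior_scores[:, 0])[0, 1]
        assert r > 0.8

    def test_loading_of_column_equal_to_score(self, rng):
        x = rng.standard_normal((20, 4))
        scores = x[:, [2]]
        loadings = column_score_correlations(x, scores)
        assert loadings[2, 0] == pytest.approx(1.0)

    def test_degenerate_score_loadings_flagged_nan(self, rng):
        x = rng.standard_normal((10, 3))
        scores = np.column_stack([x[:, 0], np.zeros(10)])
        with pytest.warns(UserWarning, match="zero"):
            loadings = column_score_correlations(x, scores)
        assert np.isnan(loadings[:, 1]).all()
        assert np.isfinite(loadings[:, 0]).all()

    def test_number_of_lvs_is_smaller_dimension(self, rng):
        res = PLSCorrelation(rng.standard_normal((26, 40)),
                             rng.standard_normal((26, 13))).fit()
        assert res.n_lv == 13

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_affine_invariance_of_solution(self, seed):
        """Shifting or positively rescaling any raw column leaves R, S, U, V unchanged."""
        g = np.random.default_rng(seed)
        x = g.standard_normal((15, 6))
        y = g.standard_normal((15, 3))
        base = PLSCorrelation(x, y).fit()
        x2 = x.copy()
        x2[:, 1] = 3.7 * x2[:, 1] + 42.0
        y2 = y.copy()
        y2[:, 0] = 0.2 * y2[:, 0] - 5.0
        alt = PLSCorrelation(x2, y2).fit()
        assert np.allclose(alt.cross_block_matrix, base.cross_block_matrix, atol=1e-8)
        assert np.allclose(alt.singular_values, base.singular_values, atol=1e-8)
        assert np.allclose(alt.brain_saliences, base.brain_saliences, atol=1e-7)
        assert np.allclose(alt.behavior_saliences, base.behavior_saliences, atol=1e-7)

    def test_subject_order_invariance(self, rng):
        x = rng.standard_normal((20, 8))
        y = rng.standard_normal((20, 4))
        base = PLSCorrelation(x, y).fit()
        perm = rng.permutation(20)
        alt = PLSCorrelation(x[perm], y[perm]).fit()
        assert np.allclose(alt.cross_block_matrix, base.cross_block_matrix, atol=1e-10)
        assert np.allclose(alt.singular_values, base.singular_values, atol=1e-10)

    def test_scale_modes_share_saliences(self, rng):
        x = rng.standard_normal((12, 5))
        y = rng.standard_normal((12, 3))
        corr = PLSCorrelation(x, y, scale="correlation").fit()
        raw = PLSCorrelation(x, y, scale="unscaled").fit()
        assert np.allclose(raw.singular_values, 11 * corr.singular_values)
        assert np.allclose(raw.brain_saliences, corr.brain_saliences, atol=1e-8)
        assert np.allclose(raw.covariance_explained, corr.covariance_explained)

    def test_summary_mentions_key_quantities(self, rng):
        res = PLSCorrelation(rng.standard_normal((10, 6)),
                             rng.standard_normal((10, 3))).fit()
        text = res.summary(0)
        assert "covariance explained" in text
        assert "singular value" in text
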