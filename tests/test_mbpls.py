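"""PCA / PLS / MBPLS: oracle comparisons and algebraic invariants."""

import numpy as np
import pytest

from mbmetab import StudyPreprocessor, fit_mbpls, fit_pca, fit_pls
from mbmetab.blocks import BlockMatrix, ResponseMatrix
from mbmetab.mbpls import block_explained_variance


def _block(values, block_id="B1"):
    values = np.asarray(values, float)
    return BlockMatrix(block_id, [f"s{i}" for i in range(values.shape[0])],
                       [f"v{j}" for j in range(values.shape[1])], values)


def _onehot(labels):
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, c in enumerate(labels):
        Y[i, classes.index(c)] = 1.0
    return ResponseMatrix(Y, [str(c) for c in classes])


# ------------------------------------------------------------------- PCA

class TestPCA:
    def test_rank_one_matrix_single_component(self, rng):
        X = np.outer(rng.normal(size=8), rng.normal(size=5))
        res = fit_pca(X, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variable_permutation_leaves_scores(self, rng):
        X = rng.normal(size=(10, 6))
        perm = rng.permutation(6)
        a = fit_pca(X, 3)
        b = fit_pca(X[:, perm], 3)
        for k in range(3):
            assert (np.allclose(a.scores[:, k], b.scores[:, k], atol=1e-10)
                    or np.allclose(a.scores[:, k], -b.scores[:, k],
                                   atol=1e-10))

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(3, 3)) + np.arange(3)
        res = fit_pca(X, 2)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            v = evecs[:, order[k]]
            got = res.loadings[:, k]
            assert (np.allclose(got, v, atol=1e-10)
                    or np.allclose(got, -v, atol=1e-10))

    def test_explained_variance_non_increasing(self, rng):
        res = fit_pca(rng.normal(size=(12, 7)), 5)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_components_beyond_rank_rejected(self, rng):
        X = np.outer(rng.normal(size=6), rng.normal(size=4))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 3)


# ------------------------------------------------------------------- PLS

def _nipals_pls_oracle(X, Y, A, tol=1e-14, max_iter=20000):
    """Brute-force NIPALS PLS2 reimplementation (independent of fit_pls)."""
    X = X.copy()
    Y = Y - Y.mean(axis=0)
    out_T, out_W = [], []
    for _ in range(A):
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        for _ in range(max_iter):
            w = X.T @ u
            w = w / np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t @ t)
            u_new = Y @ q / (q @ q)
            if np.linalg.norm(u_new - u) < tol:
                u = u_new
                break
            u = u_new
        p = X.T @ t / (t @ t)
        q = Y.T @ t / (t @ t)
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, q)
        out_T.append(t)
        out_W.append(w)
    return np.column_stack(out_T), np.column_stack(out_W)


class TestPLS:
    def test_noiseless_linear_response_exact_fit(self, rng):
        # y spans the (rank-one) signal subspace, so one component suffices
        y = rng.normal(size=(10, 1))
        X = y @ rng.normal(size=(1, 4))
        X -= X.mean(axis=0)
        model = fit_pls(X, y, 1)
        assert model.r2y_cum[0] >= 0.999

    def test_first_component_weights_proportional_to_xty(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=(9, 1))
        model = fit_pls(X, y, 1)
        Xc = X - X.mean(axis=0)
        yc = (y - y.mean(axis=0)).ravel()
        expected = Xc.T @ yc
        expected /= np.linalg.norm(expected)
        w = model.x_weights[:, 0]
        assert (np.allclose(w, expected, atol=1e-8)
                or np.allclose(w, -expected, atol=1e-8))

    def test_scores_match_brute_force_nipals_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        X -= X.mean(axis=0)
        Y = _onehot([0, 0, 1, 1, 2, 2]).Y
        model = fit_pls(X, Y, 2)
        T, W = _nipals_pls_oracle(X, Y, 2)
        for k in range(2):
            assert (np.allclose(model.x_scores[:, k], T[:, k], atol=1e-8)
                    or np.allclose(model.x_scores[:, k], -T[:, k], atol=1e-8))

    def test_training_prediction_matches_deflation(self, rng):
        X = rng.normal(size=(12, 6))
        Y = _onehot([0] * 4 + [1] * 4 + [2] * 4).Y
        model = fit_pls(X - X.mean(0), Y, 3)
        r2 = 1 - np.sum((Y - model.predict(X - X.mean(0))) ** 2) \
            / np.sum((Y - Y.mean(0)) ** 2)
        assert r2 == pytest.approx(model.r2y_cum[-1], abs=1e-8)


# ------------------------------------------------------------------ MBPLS

class TestMBPLS:
    def test_single_block_reduces_to_pls(self, rng):
        """MBPLS on one block is NIPALS PLS: scores agree to 1e-8."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.normal(size=(12, 7))
            X -= X.mean(axis=0)
            Y = _onehot([0] * 4 + [1] * 4 + [2] * 4)
            mb = fit_mbpls([_block(X)], Y, 3)
            pls = fit_pls(X, Y, 3)
            assert np.allclose(mb.super_scores, pls.x_scores, atol=1e-8)
            assert np.allclose(mb.block_weights["B1"], pls.x_weights,
                               atol=1e-8)

    def test_informative_block_dominates(self, rng):
        """Y driven by block 1; block 2 pure noise."""
        labels = [0] * 5 + [1] * 5
        Y = _onehot(labels)
        signal = np.array([[1.0] * 3 if c == 0 else [-1.0] * 3
                           for c in labels]) + 0.05 * rng.normal(size=(10, 3))
        noise = rng.normal(size=(10, 3))
        model = fit_mbpls([_block(signal - signal.mean(0), "B1"),
                           _block(noise - noise.mean(0), "B2")], Y, 1)
        assert model.block_r2["B1"][0] > model.block_r2["B2"][0]
        assert model.super_weights[0, 0] ** 2 > 0.5

    def test_default_synthetic_study_r2y(self, default_study):
        """Strong planted effects: four-component fit explains >= 90% of Y."""
        blocks, design, _ = default_study
        _, pb = StudyPreprocessor.fit(blocks)
        model = fit_mbpls(pb, design.response_matrix(), 4)
        assert model.r2y >= 0.9

    def test_super_score_orthogonality(self, small_model):
        model, _, _ = small_model
        G = model.super_scores.T @ model.super_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-8

    def test_weight_vectors_unit_norm(self, small_model):
        model, _, _ = small_model
        for bid in model.block_ids:
            W = model.block_weights[bid]
            assert np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)
        assert np.allclose(np.linalg.norm(model.super_weights, axis=0), 1.0,
                           atol=1e-10)

    def test_r2y_nondecreasing_and_bounded(self, small_model):
        model, _, _ = small_model
        assert np.all(np.diff(model.r2y_cum) >= -1e-12)
        assert 0 <= model.r2y <= 1

    def test_variable_permutation_equivariance(self, rng):
        X1 = rng.normal(size=(12, 8))
        X2 = rng.normal(size=(12, 5))
        Y = _onehot([0] * 4 + [1] * 4 + [2] * 4)
        perm = rng.permutation(8)
        a = fit_mbpls([_block(X1, "B1"), _block(X2, "B2")], Y, 2)
        b = fit_mbpls([_block(X1[:, perm], "B1"), _block(X2, "B2")], Y, 2)
        assert np.allclose(a.super_scores, b.super_scores, atol=1e-10)
        assert np.allclose(a.block_weights["B1"][perm],
                           b.block_weights["B1"], atol=1e-10)

    def test_exact_fit_when_y_in_span(self):
        """Y in the column span of the blocks and A = rank -> R2Y = 1."""
        labels = [0, 0, 1, 1, 2, 2]
        Y = _onehot(labels)
        Yc = Y.Y - Y.Y.mean(axis=0)
        model = fit_mbpls([_block(Yc[:, :2], "B1"), _block(Yc[:, 2:], "B2")],
                          Y, 2)
        assert model.r2y == pytest.approx(1.0, abs=1e-10)

    def test_refit_bit_stable(self, small_study):
        blocks, design, _ = small_study
        _, pb = StudyPreprocessor.fit(blocks)
        m1 = fit_mbpls(pb, design.response_matrix(), 4)
        m2 = fit_mbpls(pb, design.response_matrix(), 4)
        assert np.array_equal(m1.super_scores, m2.super_scores)
        for bid in m1.block_ids:
            assert np.array_equal(m1.block_weights[bid],
                                  m2.block_weights[bid])

    def test_sample_mismatch_rejected(self, rng):
        b1 = _block(rng.normal(size=(6, 3)), "B1")
        b2 = BlockMatrix("B2", [f"t{i}" for i in range(6)],
                         ["v0", "v1"], rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            fit_mbpls([b1, b2], _onehot([0, 0, 0, 1, 1, 1]), 1)


class TestBlockExplainedVariance:
    def test_rank_one_block_aligned_with_component_one(self, rng):
        labels = [0] * 3 + [1] * 3
        Y = _onehot(labels)
        yc = Y.Y[:, 0] - Y.Y[:, 0].mean()
        aligned = np.outer(yc, rng.normal(size=4))       # rank 1, spans y
        model = fit_mbpls([_block(aligned, "B1")], Y, 1)
        assert model.block_r2["B1"][0] == pytest.approx(1.0, abs=1e-10)

    def test_block_orthogonal_to_super_scores_gets_zero(self, rng):
        labels = [0] * 3 + [1] * 3
        Y = _onehot(labels)
        yc = Y.Y[:, 0] - Y.Y[:, 0].mean()
        aligned = np.outer(yc, rng.normal(size=4))
        other = rng.normal(size=(6, 3))
        other -= other.mean(0)
        # remove the component along yc: block contributes nothing to t
        other -= np.outer(yc, yc @ other) / (yc @ yc)
        model = fit_mbpls([_block(aligned, "B1"), _block(other, "B2")], Y, 1)
        assert model.block_r2["B2"][0] == pytest.approx(0.0, abs=1e-10)

    def test_incremental_sums_match_residual_computation(self, small_model,
                                                         small_study):
        """Sum over components of R2_{b,a} equals 1 - residual SS / initial
        SS, with residuals recomputed by explicit deflation."""
        model, _, _ = small_model
        blocks, design, _ = small_study
        _, pb = StudyPreprocessor.fit(blocks)
        for b in pb:
            X = b.values.copy()
            ss0 = np.sum(X ** 2)
            for a in range(model.n_components):
                t = model.super_scores[:, a]
                X -= np.outer(t, model.block_loadings[b.block_id][:, a])
            direct = 1 - np.sum(X ** 2) / ss0
            assert np.sum(model.block_r2[b.block_id]) == pytest.approx(
                direct, abs=1e-10)
            assert np.all(model.block_r2[b.block_id] >= -1e-12)
            assert np.sum(model.block_r2[b.block_id]) <= 1 + 1e-10

    def test_unfitted_access_raises(self, small_model):
        model, _, _ = small_model
        table = block_explained_variance(model)
        assert set(table) == set(model.block_ids)


class TestPredict:
    def test_training_set_reproduced(self, small_model, small_study):
        model, design, pre = small_model
        blocks, _, _ = small_study
        pb = pre.apply(blocks)
        Yhat = model.predict(pb)
        assert np.allclose(Yhat, model.fitted_y, atol=1e-10)

    def test_zero_sample_predicts_class_priors(self, small_model):
        model, _, _ = small_model
        zeros = [np.zeros((1, model.block_weights[b].shape[0]))
                 for b in model.block_ids]
        Yhat = model.predict(zeros)
        assert np.allclose(Yhat[0], model.y_mean, atol=1e-12)

    def test_held_out_sample_classified_correctly(self):
        from conftest import small_config
        from mbmetab import generate_study
        cfg = small_config(seed=11)
        blocks, design, _ = generate_study(cfg)
        hold = 3  # a CG sample
        train = np.delete(np.arange(20), hold)
        pre, tb = StudyPreprocessor.fit([b.subset_samples(train)
                                         for b in blocks])
        model = fit_mbpls(tb, design.subset(train).response_matrix(), 4)
        test = pre.apply([b.subset_samples(np.array([hold])) for b in blocks])
        pred = model.predict(test)[0]
        assert model.groups[int(np.argmax(pred))] == design.conditions[hold]

    def test_variable_mismatch_rejected(self, small_model, small_study):
        model, _, pre = small_model
        blocks, _, _ = small_study
        pb = pre.apply(blocks)
        bad = BlockMatrix(pb[0].block_id, pb[0].samples,
                          [f"other_{j}" for j in range(pb[0].n_variables)],
                          pb[0].values)
        with pytest.raises(ValueError, match="variable ids"):
            model.predict([bad] + pb[1:])
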