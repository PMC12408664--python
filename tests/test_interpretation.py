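"""DEG ranking, gene-set scores, the random-gene-set null, integrated gradients."""

import numpy as np
import pytest

from scdrp.autodiff import Tensor
from scdrp.dae import DAEConfig, DAEModel
from scdrp.attention import AttentionConfig, PredictorModel
from scdrp.interpretation import (
    find_degs,
    gene_set_score,
    integrated_gradients,
    random_geneset_null,
    score_correlation,
)

from conftest import make_matrix


def lognorm_matrix(values):
    return make_matrix(values, layer="lognorm")


class TestFindDegs:
    def test_planted_marker_ranks_first(self, rng):
        X = rng.normal(1.0, 0.5, size=(100, 30))
        labels = np.array([1] * 50 + [0] * 50)
        X[:50, 7] += 3.0  # strong sensitive-up marker
        degs = find_degs(lognorm_matrix(np.abs(X) + 0.1), labels)
        assert degs["sensitive_up"][0] == "g7"

    def test_identical_gene_absent_from_both_lists(self, rng):
        X = rng.normal(2.0, 0.5, size=(40, 5))
        X[:, 2] = 1.234  # constant gene, zero effect
        labels = np.array([1] * 20 + [0] * 20)
        degs = find_degs(lognorm_matrix(X - X.min() + 0.1), labels)
        assert "g2" not in degs["sensitive_up"] + degs["resistant_up"]

    def test_label_permutation_yields_almost_no_degs(self, rng):
        X = np.abs(rng.normal(2.0, 0.5, size=(60, 50)))
        from scipy.stats import ranksums
        from statsmodels.stats.multitest import multipletests

        sig_frac = []
        for _ in range(20):
            labels = rng.permutation(np.array([1] * 30 + [0] * 30))
            p = [ranksums(X[labels == 1, j], X[labels == 0, j]).pvalue for j in range(50)]
            padj = multipletests(p, method="fdr_bh")[1]
            sig_frac.append(np.mean(padj < 0.05))
        assert np.mean(sig_frac) <= 0.01

    def test_small_class_rejected(self, rng):
        X = lognorm_matrix(np.abs(rng.normal(size=(10, 5))))
        with pytest.raises(ValueError, match="at least 3"):
            find_degs(X, np.array([1, 1] + [0] * 8))


class TestGeneSetScore:
    def test_constant_matrix_scores_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            gs = gene_set_score(lognorm_matrix(np.full((4, 3), 2.0)), ["g0", "g1"])
        assert np.allclose(gs.scores, 0.0)

    def test_singleton_set_equals_gene_zscore(self, rng):
        X = rng.normal(size=(10, 4))
        gs = gene_set_score(lognorm_matrix(X), ["g2"])
        expected = (X[:, 2] - X[:, 2].mean()) / X[:, 2].std()
        assert np.allclose(gs.scores, expected, atol=1e-12)

    def test_two_gene_toy_hand_computed(self):
        X = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]])
        gs = gene_set_score(lognorm_matrix(X), ["g0", "g1"])
        z0 = (X[:, 0] - 2.0) / X[:, 0].std()
        z1 = (X[:, 1] - 6.0) / X[:, 1].std()
        assert np.allclose(gs.scores, (z0 + z1) / 2, atol=1e-12)

    def test_gene_order_within_set_is_irrelevant(self, rng):
        X = lognorm_matrix(rng.normal(size=(8, 5)))
        a = gene_set_score(X, ["g1", "g3", "g4"]).scores
        b = gene_set_score(X, ["g4", "g1", "g3"]).scores
        assert np.allclose(a, b, atol=1e-12)  # up to summation order

    def test_empty_intersection_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            gene_set_score(lognorm_matrix(rng.normal(size=(4, 2))), ["nope"])


class TestScoreCorrelation:
    def test_identity_and_sign_flip(self, rng):
        X = lognorm_matrix(rng.normal(size=(20, 6)))
        gs = gene_set_score(X, ["g0", "g1"])
        r, r2 = score_correlation(gs, gs)
        assert r == pytest.approx(1.0)
        flipped = gene_set_score(X, ["g0", "g1"])
        flipped.scores = -flipped.scores
        r, _ = score_correlation(gs, flipped)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_have_small_correlation(self, rng):
        X = lognorm_matrix(rng.normal(size=(1000, 4)))
        a = gene_set_score(X, ["g0"])
        b = gene_set_score(X, ["g2"])
        r, _ = score_correlation(a, b)
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self, rng):
        X = lognorm_matrix(rng.normal(size=(5, 3)))
        a = gene_set_score(X, ["g0"])
        b = gene_set_score(X, ["g1"])
        b.scores = np.zeros(5)
        with pytest.raises(ValueError, match="zero variance"):
            score_correlation(a, b)


class TestRandomGenesetNull:
    @staticmethod
    def labeled_matrix(rng, n=60, g=40):
        X = np.abs(rng.normal(2.0, 0.5, size=(n, g)))
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        X[labels == 1, :5] += 2.0  # genes g0..g4 mark the sensitive class
        return lognorm_matrix(X), labels

    def test_add_one_estimator_boundaries(self, rng):
        X, labels = self.labeled_matrix(rng)
        # with a strongly informative DEG list the observed r beats most nulls
        obs, nulls, p = random_geneset_null(
            X, labels, labels, deg_list=["g0", "g1", "g2"], n_trials=100, seed=0
        )
        assert p >= 1 / 101  # never exactly zero
        assert len(nulls) == 100
        assert p == (1 + np.sum(nulls >= obs)) / 101

    def test_single_trial_below_observed(self, rng):
        X, labels = self.labeled_matrix(rng)
        obs, nulls, p = random_geneset_null(
            X, labels, labels, deg_list=["g0", "g1"], n_trials=1, seed=3
        )
        if nulls[0] < obs:
            assert p == pytest.approx(0.5)

    def test_deterministic_under_seed(self, rng):
        X, labels = self.labeled_matrix(rng)
        a = random_geneset_null(X, labels, labels, deg_list=["g0"], n_trials=20, seed=9)
        b = random_geneset_null(X, labels, labels, deg_list=["g0"], n_trials=20, seed=9)
        assert np.array_equal(a[1], b[1]) and a[2] == b[2]

    def test_empty_deg_list_rejected(self, rng):
        X, labels = self.labeled_matrix(rng)
        with pytest.raises(ValueError, match="empty DEG list"):
            random_geneset_null(X, labels, labels, deg_list=[], n_trials=5, seed=0)


def linear_sigmoid_model(w, seed=0):
    """Identity 'encoder' + one-layer sigmoid predictor: F(x) = sigmoid(w.x)."""
    G = len(w)
    dae = DAEModel(DAEConfig(input_dim=G, encoder_dims=[], bottleneck=G,
                             noise_rate=0.0, dropout=0.0, epochs=1, seed=seed))
    dae.encoder.layers[0].W.data = np.eye(G)
    dae.encoder.layers[0].b.data[:] = 0.0
    pred = PredictorModel(AttentionConfig(n_heads=0, n_tokens=1, token_dim=G,
                                          predictor_dims=[], dropout=0.0, seed=seed))
    pred.mlp.layers[0].W.data = np.asarray(w, dtype=float).reshape(G, 1)
    pred.mlp.layers[0].b.data[:] = 0.0
    return dae, pred


class TestIntegratedGradients:
    def test_sigmoid_of_linear_closed_form(self, rng):
        # F(x) = sigmoid(w.x), baseline 0: IG_i = x_i w_i (F(x) - F(0)) / (w.x)
        w = rng.normal(size=6)
        dae, pred = linear_sigmoid_model(w)
        X = rng.normal(size=(4, 6))
        result = integrated_gradients(dae, pred, X, n_steps=4000)
        for i in range(4):
            wx = float(w @ X[i])
            Fx = 1 / (1 + np.exp(-wx))
            expected = X[i] * w * (Fx - 0.5) / wx
            assert np.allclose(result.attributions[i], expected, atol=1e-6)

    def test_constant_model_attributes_nothing(self, rng):
        dae, pred = linear_sigmoid_model(np.zeros(5))
        result = integrated_gradients(dae, pred, rng.normal(size=(3, 5)), n_steps=50)
        assert np.allclose(result.attributions, 0.0)
        assert np.allclose(result.completeness_residual, 0.0, atol=1e-12)

    def test_attributions_scale_with_input_for_linear_map(self, rng):
        w = rng.normal(size=5)
        dae, pred = linear_sigmoid_model(w)
        x = rng.normal(size=(1, 5)) * 0.01  # sigmoid near-linear regime
        a1 = integrated_gradients(dae, pred, x, n_steps=200).attributions
        a2 = integrated_gradients(dae, pred, 2 * x, n_steps=200).attributions
        assert np.allclose(a2, 2 * a1, rtol=1e-2)

    def test_completeness_on_trained_model(self, tiny_trained):
        result, _, _ = tiny_trained
        rng = np.random.default_rng(5)
        X = np.abs(rng.normal(1.0, 0.5, size=(10, 60)))
        att = integrated_gradients(result.model.sc_dae, result.model.predictor, X,
                                   n_steps=1000)
        from scdrp.attention import predict_proba
        from scdrp.dae import encode

        fx = predict_proba(result.model.predictor, encode(result.model.sc_dae, X))
        fb = predict_proba(result.model.predictor,
                           encode(result.model.sc_dae, np.zeros((1, 60))))[0]
        tol = 0.01 * np.abs(fx - fb) + 1e-4
        assert np.all(att.completeness_residual < tol)

    def test_bad_baseline_width_rejected(self, rng):
        dae, pred = linear_sigmoid_model(np.ones(4))
        with pytest.raises(ValueError, match="baseline"):
            integrated_gradients(dae, pred, rng.normal(size=(2, 4)), baseline=np.zeros(3))
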