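"""MMD estimator, Louvain clustering, cluster regularizer, DaNN training."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scdrp.datamodel import ExpressionMatrix
from scdrp.transfer import (
    DaNNConfig,
    MMDConfig,
    align_genes,
    binarize_scores,
    cluster_cells,
    cluster_regularizer,
    dann_loss,
    load_bundle,
    save_bundle,
)

from conftest import make_matrix


def mmd_double_sum_oracle(X, Y, kernel):
    """O((n+m)^2) brute-force kernel double sum."""
    n, m = len(X), len(Y)
    kxx = np.mean([[kernel(X[i], X[j]) for j in range(n)] for i in range(n)])
    kyy = np.mean([[kernel(Y[i], Y[j]) for j in range(m)] for i in range(m)])
    kxy = np.mean([[kernel(X[i], Y[j]) for j in range(m)] for i in range(n)])
    return kxx + kyy - 2 * kxy


class TestMMD:
    def test_identical_point_sets_give_zero(self, rng):
        from scdrp.transfer import mmd

        Z = rng.normal(size=(15, 4))
        assert abs(mmd(Z, Z.copy())) < 1e-10
        assert abs(mmd(Z, Z.copy(), MMDConfig(kernel="linear"))) < 1e-10

    def test_linear_kernel_closed_form(self, rng):
        from scdrp.transfer import mmd

        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(12, 3))
        expected = np.sum((X.mean(axis=0) - Y.mean(axis=0)) ** 2)
        assert mmd(X, Y, MMDConfig(kernel="linear")) == pytest.approx(expected, abs=1e-10)

    def test_rbf_matches_double_sum_oracle(self, rng):
        from scdrp.transfer import _rbf_bandwidths, mmd

        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(12, 3)) + 1.0
        cfg = MMDConfig()
        bws = _rbf_bandwidths(X, Y, cfg)

        def kernel(a, b):
            d2 = np.sum((a - b) ** 2)
            return np.mean([np.exp(-d2 / bw) for bw in bws])

        assert mmd(X, Y, cfg) == pytest.approx(mmd_double_sum_oracle(X, Y, kernel), abs=1e-10)

    def test_width_mismatch_rejected(self, rng):
        from scdrp.transfer import mmd

        with pytest.raises(ValueError, match="width"):
            mmd(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))


class TestClustering:
    def test_two_separated_blobs_recovered_exactly(self, rng):
        blob1 = rng.normal(0, 1, size=(20, 3))
        blob2 = rng.normal(0, 1, size=(20, 3)) + 30.0  # 10 sigma separation and then some
        Z = np.vstack([blob1, blob2])
        labels = cluster_cells(Z, resolution=1.0, n_neighbors=15, seed=0)
        truth = np.array([0] * 20 + [1] * 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_point_cloud_is_one_cluster(self):
        Z = np.tile([[1.0, 2.0]], (12, 1))
        labels = cluster_cells(Z, n_neighbors=3, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_under_seed(self, rng):
        Z = rng.normal(size=(40, 4))
        a = cluster_cells(Z, n_neighbors=8, seed=5)
        b = cluster_cells(Z, n_neighbors=8, seed=5)
        assert np.array_equal(a, b)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError, match="NN graph"):
            cluster_cells(rng.normal(size=(5, 2)), n_neighbors=10)


class TestClusterRegularizer:
    def test_identical_cells_give_zero(self):
        Z = np.tile([[2.0, 1.0]], (6, 1))
        assert cluster_regularizer(Z, np.zeros(6)) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair_hand_computed(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        # centroid (0.5, 0.5); cos(cell, centroid) = cos 45 degrees
        expected = 1 - np.cos(np.pi / 4)
        assert cluster_regularizer(Z, np.zeros(2)) == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance(self, rng):
        Z = rng.normal(size=(20, 5))
        clusters = rng.integers(0, 3, size=20)
        assert cluster_regularizer(Z, clusters) == pytest.approx(
            cluster_regularizer(Z * 37.5, clusters), abs=1e-10
        )

    def test_zero_norm_vector_warns(self):
        Z = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero-norm"):
            cluster_regularizer(Z, np.zeros(2))


class TestDannLossAndBinarize:
    def test_weighted_sum(self):
        cfg = DaNNConfig(omega=0.5, theta=0.1)
        assert dann_loss(1.0, 2.0, 3.0, cfg) == pytest.approx(2.3)
        cfg0 = DaNNConfig(omega=0.0, theta=0.0)
        assert dann_loss(1.7, 99.0, 99.0, cfg0) == pytest.approx(1.7)

    def test_binarize_thresholds(self):
        scores = np.array([0.3, 0.7, 0.5, 0.0, 1.0])
        assert list(binarize_scores(scores)) == [0, 1, 1, 0, 1]

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="≥ 0"):
            DaNNConfig(omega=-0.1)


class TestAlignGenes:
    def test_inner_join_keeps_bulk_order(self, rng):
        bulk = ExpressionMatrix(rng.random((3, 4)), ["a", "b", "c"],
                                ["g3", "g1", "g2", "g0"], domain="bulk", layer="lognorm")
        sc = make_matrix(rng.integers(0, 5, size=(2, 3)))  # genes g0,g1,g2
        b2, s2 = align_genes(bulk, sc)
        assert b2.gene_ids == ["g1", "g2", "g0"]
        assert s2.gene_ids == ["g1", "g2", "g0"]

    def test_empty_intersection_rejected(self, rng):
        bulk = ExpressionMatrix(rng.random((2, 2)), ["a", "b"], ["x1", "x2"],
                                domain="bulk", layer="lognorm")
        sc = make_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match="empty gene intersection"):
            align_genes(bulk, sc)


class TestJointTraining:
    def test_loss_trace_decomposes_exactly(self, tiny_trained):
        result, _, _ = tiny_trained
        dann = result.model.dann
        for step in result.loss_trace:
            expected = step["class"] + dann.omega * step["mmd"] + dann.theta * step["regularizer"]
            assert step["total"] == pytest.approx(expected, abs=1e-6)

    def test_scores_cover_every_cell_in_unit_interval(self, tiny_trained):
        result, y_sc, _ = tiny_trained
        s = result.scores.scores
        assert len(s) == len(y_sc.labels)
        assert np.all((s >= 0) & (s <= 1))
        assert result.scores.provenance == "predicted"

    def test_bulk_class_loss_decreases(self, tiny_trained):
        result, _, _ = tiny_trained
        trace = result.loss_trace
        first = np.mean([t["class"] for t in trace[:4]])
        last = np.mean([t["class"] for t in trace[-4:]])
        assert last < first

    def test_bundle_roundtrip_reproduces_scores(self, tiny_trained, tmp_path):
        from scdrp.attention import predict_proba
        from scdrp.dae import encode

        result, _, _ = tiny_trained
        save_bundle(result.model, str(tmp_path / "bundle"))
        back = load_bundle(str(tmp_path / "bundle"))
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, len(back.gene_ids)))
        a = predict_proba(result.model.predictor, encode(result.model.sc_dae, X))
        b = predict_proba(back.predictor, encode(back.sc_dae, X))
        assert np.array_equal(a, b)

    def test_missing_bundle_dir_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="model bundle not found"):
            load_bundle(str(tmp_path / "nope"))
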