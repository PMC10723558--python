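import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mint.categorize import (
    fit_pseudo_labels,
    predict_category,
    scaled_min_cluster_size,
    train_category_predictor,
)
from mint.errors import (
    DimensionMismatchError,
    SingleCategoryError,
    TooFewPointsError,
)
from mint.nn import MLPConfig


def two_blobs(n=200, sep=50.0, dim=8, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n, dim))
    b = rng.normal(sep, 1.0, (n, dim))
    X = np.vstack([a, b])
    truth = np.array([0] * n + [1] * n)
    return X, truth


class TestFitPseudoLabels:
    def test_two_separated_blobs_ari_one(self):
        X, truth = two_blobs()
        model, pseudo = fit_pseudo_labels(
            X, clusterer_params={"min_cluster_size": 20}, seed=0
        )
        assert model.n_clusters == 2
        hard = np.array([p.hard_label for p in pseudo])
        assert adjusted_rand_score(truth, hard) == 1.0

    def test_membership_contract(self):
        X, _ = two_blobs(seed=1)
        _, pseudo = fit_pseudo_labels(
            X, clusterer_params={"min_cluster_size": 20}, seed=0
        )
        for p in pseudo:
            assert np.all(p.membership >= 0) and np.all(p.membership <= 1)
            assert p.membership.sum() == pytest.approx(1.0, abs=1e-9)
            assert p.hard_label == int(np.argmax(p.membership))

    def test_identical_points_single_cluster_no_crash(self):
        X = np.ones((100, 4))
        model, pseudo = fit_pseudo_labels(
            X, clusterer_params={"min_cluster_size": 10}, seed=0
        )
        assert model.n_clusters >= 1
        assert all(np.isfinite(p.membership).all() for p in pseudo)

    def test_too_few_points_raises(self):
        with pytest.raises(TooFewPointsError):
            fit_pseudo_labels(
                np.zeros((5, 4)), clusterer_params={"min_cluster_size": 10}
            )

    def test_deterministic_under_seed(self):
        X, _ = two_blobs(seed=2)
        m1, p1 = fit_pseudo_labels(X, clusterer_params={"min_cluster_size": 20}, seed=3)
        m2, p2 = fit_pseudo_labels(X, clusterer_params={"min_cluster_size": 20}, seed=3)
        np.testing.assert_array_equal(
            np.array([p.hard_label for p in p1]), np.array([p.hard_label for p in p2])
        )
        np.testing.assert_allclose(
            np.vstack([p.membership for p in p1]),
            np.vstack([p.membership for p in p2]),
        )

    def test_min_cluster_size_scaling(self):
        assert scaled_min_cluster_size(80000) == 1000
        assert scaled_min_cluster_size(2000) == 25
        assert scaled_min_cluster_size(100) == 10


class TestCategoryPredictor:
    @pytest.fixture(scope="class")
    def blob_setup(self):
        X, truth = two_blobs(n=150, seed=4)
        model, pseudo = fit_pseudo_labels(
            X, clusterer_params={"min_cluster_size": 20}, seed=0
        )
        cfg = MLPConfig(hidden_size=32, max_epochs=60, patience=10, dropout=0.1)
        predictor = train_category_predictor(X, pseudo, config=cfg, seed=0)
        return X, truth, pseudo, predictor, cfg

    def test_holdout_accuracy_on_separable_data(self, blob_setup):
        X, truth, pseudo, predictor, _ = blob_setup
        probe, probe_truth = two_blobs(n=100, seed=9)
        pred = predict_category(predictor, probe).argmax(axis=1)
        assert adjusted_rand_score(probe_truth, pred) >= 0.9

    def test_probabilities_sum_to_one(self, blob_setup):
        X, _, _, predictor, _ = blob_setup
        probs = predict_category(predictor, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_training_exemplar_recovers_pseudo_label(self, blob_setup):
        X, _, pseudo, predictor, _ = blob_setup
        # deep-inside exemplar: highest own-membership point per cluster
        member = np.vstack([p.membership for p in pseudo])
        for c in range(member.shape[1]):
            i = int(np.argmax(member[:, c]))
            pred = predict_category(predictor, X[i]).argmax()
            assert pred == pseudo[i].hard_label

    def test_identical_inputs_identical_outputs(self, blob_setup):
        X, *_ = blob_setup
        predictor = blob_setup[3]
        a = predict_category(predictor, X[0])
        b = predict_category(predictor, X[0])
        np.testing.assert_array_equal(a, b)

    def test_duplicated_training_set_same_hard_predictions(self, blob_setup):
        X, _, pseudo, _, cfg = blob_setup
        probe, _ = two_blobs(n=60, seed=12)
        p1 = train_category_predictor(X, pseudo, config=cfg, seed=0)
        p2 = train_category_predictor(
            np.vstack([X, X]), pseudo + pseudo, config=cfg, seed=0
        )
        h1 = predict_category(p1, probe).argmax(axis=1)
        h2 = predict_category(p2, probe).argmax(axis=1)
        assert (h1 == h2).mean() >= 0.99

    def test_single_category_raises(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        from mint.categorize import PseudoLabel

        pseudo = [PseudoLabel(np.array([1.0]), 0, False) for _ in range(50)]
        with pytest.raises(SingleCategoryError):
            train_category_predictor(X, pseudo, seed=0)

    def test_dimension_mismatch_raises(self, blob_setup):
        predictor = blob_setup[3]
        with pytest.raises(DimensionMismatchError):
            predict_category(predictor, np.zeros(3))

    def test_bce_mode_outputs_distribution(self, blob_setup):
        X, _, pseudo, _, cfg = blob_setup
        predictor = train_category_predictor(
            X, pseudo, config=cfg, seed=0, loss_mode="bce"
        )
        probs = predict_category(predictor, X[:10])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestHyperparameterRobustness:
    def test_ari_stable_across_reference_grid(self, trained_embedding,
                                              benchmark_corpus):
        """One-factor-at-a-time sweep of the reference hyperparameter grid
        (dimension, n_neighbors, min_samples, selection epsilon): ARI vs
        planted truth must vary by < 0.1.  Run on a 1000-item subsample to
        stay inside the suite's time budget."""
        from mint.embeddings import (
            WordAverageEncoder,
            build_context_sentence,
            embed_context,
        )

        enc = WordAverageEncoder(trained_embedding)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(benchmark_corpus.items), size=1000, replace=False)
        items = [benchmark_corpus.items[i] for i in idx]
        ctx = np.vstack(
            [
                embed_context(
                    enc, build_context_sentence(it.name, it.ingredients)
                )
                for it in items
            ]
        )
        truth = np.array([it.true_category for it in items])

        def ari(rp=None, cp=None):
            model, pseudo = fit_pseudo_labels(
                ctx, reducer_params=rp, clusterer_params=cp, seed=2
            )
            hard = np.array([p.hard_label for p in pseudo])
            return adjusted_rand_score(truth, hard)

        aris = [ari()]
        for dim in (10, 50):
            aris.append(ari({"n_components": dim}))
        for nn_ in (10, 20):
            aris.append(ari({"n_neighbors": nn_}))
        for ms in (20, 50):
            aris.append(ari(None, {"min_samples": ms}))
        for eps in (0.05, 0.10):
            aris.append(ari(None, {"cluster_selection_epsilon": eps}))
        assert max(aris) - min(aris) < 0.1, aris
        assert min(aris) >= 0.8


class TestEndToEndRecovery:
    def test_planted_category_recovery(self, fitted_benchmark, benchmark_corpus):
        m = fitted_benchmark
        truth = benchmark_corpus.true_categories()
        # pseudo-labels on the training split
        hard = np.array([p.hard_label for p in m.pseudo_labels])
        assert adjusted_rand_score(truth[m.train_idx], hard) >= 0.8
        # name-only predictor end-to-end on held-out items
        pred = predict_category(m.predictor, m.name_vectors[m.test_idx]).argmax(1)
        assert adjusted_rand_score(truth[m.test_idx], pred) >= 0.8
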