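import numpy as np
import pytest

from mint.categorize import PseudoLabel
from mint.errors import EmptyInputError, EmptyNameError, LengthMismatchError
from mint.nn import MLP, MLPConfig
from mint.regression import (
    CategoryStats,
    fcwm_predict,
    finetune_per_category,
    mc_dropout_samples,
    predict_with_uncertainty,
    train_global_regressor,
)


class TestFCWM:
    def test_one_hot_identity(self):
        stats = CategoryStats(means=np.array([0.3, 0.7, 1.1]), counts=np.ones(3))
        for k in range(3):
            p = np.zeros(3)
            p[k] = 1.0
            assert fcwm_predict(p, stats) == stats.means[k]

    def test_hand_arithmetic(self):
        stats = CategoryStats(means=np.array([1.0, 0.5]), counts=np.ones(2))
        assert fcwm_predict(np.array([0.7, 0.3]), stats) == pytest.approx(0.85)

    def test_uniform_is_mean(self):
        means = np.array([0.2, 0.8, 1.4, 2.0])
        stats = CategoryStats(means=means, counts=np.ones(4))
        assert fcwm_predict(np.full(4, 0.25), stats) == pytest.approx(means.mean())

    def test_matches_brute_force_1000_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            p = rng.dirichlet(np.ones(k))
            tm = rng.uniform(0, 3, size=k)
            stats = CategoryStats(means=tm, counts=np.ones(k, dtype=int))
            brute = sum(p[i] * tm[i] for i in range(k))
            assert fcwm_predict(p, stats) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch_raises(self):
        stats = CategoryStats(means=np.array([1.0, 0.5]), counts=np.ones(2))
        with pytest.raises(LengthMismatchError):
            fcwm_predict(np.array([1.0, 0.0, 0.0]), stats)

    def test_unnormalized_probs_rejected(self):
        stats = CategoryStats(means=np.array([1.0, 0.5]), counts=np.ones(2))
        with pytest.raises(ValueError):
            fcwm_predict(np.array([0.7, 0.7]), stats)

    def test_from_labels(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0])
        labels = np.array([0, 0, 1, 1])
        stats = CategoryStats.from_labels(scores, labels, 2)
        np.testing.assert_allclose(stats.means, [1.5, 6.5])
        np.testing.assert_array_equal(stats.counts, [2, 2])


@pytest.fixture(scope="module")
def toy_regression():
    """Linear-ish mapping from 8-d vectors to scores, 4 latent categories."""
    rng = np.random.default_rng(1)
    n, dim = 400, 8
    cats = rng.integers(0, 4, size=n)
    centers = rng.normal(0, 2, size=(4, dim))
    X = centers[cats] + rng.normal(0, 0.3, size=(n, dim))
    cat_scores = np.array([0.3, 0.7, 1.1, 1.5])
    y = cat_scores[cats]
    pseudo = [
        PseudoLabel(np.eye(4)[c], int(c), False) for c in cats
    ]
    cfg = MLPConfig(
        hidden_size=64, dropout=0.1, patience=25, max_epochs=300, batch_size=32
    )
    return X, y, cats, pseudo, cfg


class TestGlobalRegressor:
    def test_constant_targets_fit_and_warn(self, caplog):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        # L2 from the reference grid strong enough to shrink to the constant
        cfg = MLPConfig(
            hidden_size=16, max_epochs=400, patience=50, dropout=0.0,
            batch_size=16, l2=1e-2, learning_rate=1e-2,
        )
        with caplog.at_level("WARNING"):
            reg = train_global_regressor(X, np.full(80, 0.5), config=cfg, seed=0)
        assert "degenerate" in caplog.text
        pred = reg.predict(rng.normal(size=(20, 4)))
        np.testing.assert_allclose(pred, 0.5, atol=0.5 * 1e-2)

    def test_deterministic_category_function_r2(self, toy_regression):
        X, y, cats, _, cfg = toy_regression
        reg = train_global_regressor(X[:320], y[:320], config=cfg, seed=0)
        pred = reg.predict(X[320:])
        from mint.evaluate import regression_metrics

        assert regression_metrics(y[320:], pred).r_squared >= 0.8

    def test_fixed_seed_identical_rmse(self, toy_regression):
        X, y, _, _, cfg = toy_regression
        a = train_global_regressor(X, y, config=cfg, seed=3).predict(X)
        b = train_global_regressor(X, y, config=cfg, seed=3).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_too_few_items_raises(self):
        with pytest.raises(EmptyInputError):
            train_global_regressor(np.zeros((10, 4)), np.zeros(10))


class TestFinetune:
    def test_zero_epochs_is_noop(self, toy_regression):
        X, y, cats, pseudo, cfg = toy_regression
        base = train_global_regressor(X, y, config=cfg, seed=0)
        ens = finetune_per_category(base, X, y, pseudo, config=cfg, epochs=0)
        for c in range(4):
            np.testing.assert_array_equal(
                ens.model_for(c).forward(X[:20]), base.net.forward(X[:20])
            )

    def test_small_category_falls_back_to_base(self, toy_regression):
        X, y, cats, pseudo, cfg = toy_regression
        base = train_global_regressor(X, y, config=cfg, seed=0)
        ens = finetune_per_category(
            base, X, y, pseudo, config=cfg, min_finetune_items=10**6
        )
        assert ens.fallback_categories == [0, 1, 2, 3]
        np.testing.assert_allclose(
            ens.predict_routed(X[:10], cats[:10]), base.predict(X[:10]), rtol=1e-12
        )

    def test_finetuning_reduces_per_category_training_residual(self, toy_regression):
        X, y, cats, pseudo, cfg = toy_regression
        base = train_global_regressor(X, y, config=cfg, seed=0)
        ens = finetune_per_category(base, X, y, pseudo, config=cfg, seed=0)
        worse = 0
        for c in range(4):
            mask = cats == c
            base_mse = np.mean((base.predict(X[mask]) - y[mask]) ** 2)
            ft_mse = np.mean(
                (ens.model_for(c).forward(X[mask])[:, 0] - y[mask]) ** 2
            )
            if ft_mse > base_mse:
                worse += 1
        assert worse == 0

    def test_mixture_prediction_matches_onehot_routing(self, toy_regression):
        X, y, cats, pseudo, cfg = toy_regression
        base = train_global_regressor(X, y, config=cfg, seed=0)
        ens = finetune_per_category(base, X, y, pseudo, config=cfg, seed=0)
        P = np.eye(4)[cats[:20]]
        np.testing.assert_allclose(
            ens.predict_mixture(X[:20], P),
            ens.predict_routed(X[:20], cats[:20]),
            rtol=1e-10,
        )


class TestMCDropout:
    @pytest.fixture(scope="class")
    def tiny_models(self, small_corpus, mlp_config):
        from mint.workflow import fit_mint

        cfg = mlp_config.replace(max_epochs=60, patience=10)
        return fit_mint(small_corpus, seed=0, mlp_config=cfg, embed_epochs=2,
                        embed_dim=32)

    def test_zero_dropout_degenerate_interval(self, tiny_models):
        m = tiny_models
        net = m.ensemble.base.net.copy()
        net.config = net.config.replace(dropout=0.0)
        x = m.name_vectors[0]
        samples = mc_dropout_samples(net, x, 20, np.random.default_rng(0))
        assert np.ptp(samples) == 0.0
        assert samples[0] == net.forward(x)[0, 0]

    def test_predict_with_uncertainty_contract(self, tiny_models, small_corpus):
        m = tiny_models
        res = predict_with_uncertainty(
            m.ensemble, m.predictor, m.embedding,
            small_corpus.items[0].name, n_mc=50, seed=0,
        )
        assert res.ci_low <= res.point_estimate <= res.ci_high
        assert 0 <= res.category_confidence <= 1
        assert res.predicted_category in range(m.ensemble.n_categories)
        assert res.ci_high > res.ci_low  # dropout > 0 -> non-degenerate

    def test_n_mc_one_degenerates_to_single_draw(self, tiny_models, small_corpus):
        m = tiny_models
        res = predict_with_uncertainty(
            m.ensemble, m.predictor, m.embedding,
            small_corpus.items[0].name, n_mc=1, seed=0,
        )
        assert res.ci_low == res.point_estimate == res.ci_high

    def test_zero_dropout_interval_via_api(self, tiny_models, small_corpus):
        m = tiny_models
        ens = m.ensemble
        saved = {c: ens.models[c] for c in ens.models}
        try:
            for c in ens.models:
                net = ens.models[c].copy()
                net.config = net.config.replace(dropout=0.0)
                ens.models[c] = net
            res = predict_with_uncertainty(
                ens, m.predictor, m.embedding, small_corpus.items[0].name,
                n_mc=25, seed=0,
            )
            assert res.ci_high - res.ci_low == 0.0
        finally:
            ens.models.update(saved)

    def test_empty_name_raises(self, tiny_models):
        m = tiny_models
        with pytest.raises(EmptyNameError):
            predict_with_uncertainty(m.ensemble, m.predictor, m.embedding, "  ")

    def test_normal_ci_method(self, tiny_models, small_corpus):
        m = tiny_models
        res = predict_with_uncertainty(
            m.ensemble, m.predictor, m.embedding, small_corpus.items[0].name,
            n_mc=50, seed=0, ci_method="normal",
        )
        assert res.ci_low <= res.point_estimate <= res.ci_high

    def test_never_nan_for_arbitrary_names(self, tiny_models):
        m = tiny_models
        for name in ("utterly unseen wordage", "日本語テスト", "x", "Buddha's Delight"):
            res = predict_with_uncertainty(
                m.ensemble, m.predictor, m.embedding, name, n_mc=10, seed=0
            )
            assert np.isfinite(res.point_estimate)
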