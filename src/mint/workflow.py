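"""End-to-end fitting of all stages on an in-memory corpus.

Shared by the ablation harness, the file-based pipeline and the test
suite.  The split discipline: 20% of items are held out for testing;
early stopping inside each network uses a further 20% of the remaining
training items, so the two validation sets are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .categorize import (
    CategoryPredictor,
    ClusterModel,
    PseudoLabel,
    fit_pseudo_labels,
    predict_category,
    train_category_predictor,
)
from .embeddings import (
    FoodEmbeddingModel,
    WordAverageEncoder,
    build_context_sentence,
    embed_context,
    embed_names,
    train_embedding_model,
)
from .evaluate import MetricReport, regression_metrics
from .nn import MLPConfig
from .regression import (
    CategoryStats,
    FinetunedEnsemble,
    GlobalRegressor,
    finetune_per_category,
    train_global_regressor,
)
from .synth import SyntheticCorpus, generate_recipe_corpus

logger = logging.getLogger(__name__)


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-label random split; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train, test = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


@dataclass
class MintModels:
    """Every fitted artifact of one end-to-end run."""

    embedding: FoodEmbeddingModel
    cluster_model: ClusterModel
    pseudo_labels: list[PseudoLabel]     # aligned with train_idx
    predictor: CategoryPredictor
    stats: CategoryStats
    global_regressor: GlobalRegressor
    ensemble: FinetunedEnsemble
    name_vectors: np.ndarray             # all items
    scores: np.ndarray                   # all items (ground truth)
    train_idx: np.ndarray
    test_idx: np.ndarray
    variant: str = "rrr_macro"
    extras: dict = field(default_factory=dict)


def fit_mint(
    corpus: SyntheticCorpus,
    seed: int = 0,
    variant: str = "rrr_macro",
    embed_dim: int = 48,
    embed_epochs: int = 4,
    mlp_config: MLPConfig | None = None,
    test_fraction: float = 0.2,
    reducer_params: dict | None = None,
    clusterer_params: dict | None = None,
    min_finetune_items: int = 20,
) -> MintModels:
    """Train embeddings, pseudo-labels, category predictor and regressors."""
    if not corpus.documents:
        generate_recipe_corpus(corpus)
    if variant == "rrr_macro":
        scores = corpus.rrr_macro()
    else:
        from .nutrients import compute_rrr

        scores = np.array([compute_rrr(it.profile).value for it in corpus.items])

    embedding = train_embedding_model(
        corpus.documents, dimension=embed_dim, epochs=embed_epochs, seed=seed
    )
    names = corpus.names()
    name_vectors = embed_names(embedding, names)

    train_idx, test_idx = stratified_split(
        corpus.true_categories(), test_fraction, seed=seed + 1
    )

    encoder = WordAverageEncoder(embedding)
    context_vectors = np.vstack(
        [
            embed_context(
                encoder,
                build_context_sentence(
                    corpus.items[i].name, corpus.items[i].ingredients
                ),
            )
            for i in train_idx
        ]
    )
    cluster_model, pseudo_labels = fit_pseudo_labels(
        context_vectors,
        reducer_params=reducer_params,
        clusterer_params=clusterer_params,
        seed=seed + 2,
    )

    cfg = mlp_config or MLPConfig()
    predictor = train_category_predictor(
        name_vectors[train_idx], pseudo_labels, config=cfg, seed=seed + 3
    )

    hard = np.array(
        [p.hard_label for p in pseudo_labels if not p.is_noise], dtype=int
    )
    keep = np.array([not p.is_noise for p in pseudo_labels], dtype=bool)
    stats = CategoryStats.from_labels(
        scores[train_idx][keep], hard, cluster_model.n_clusters
    )

    global_regressor = train_global_regressor(
        name_vectors[train_idx],
        scores[train_idx],
        config=cfg,
        seed=seed + 4,
        variant=variant,
    )
    ensemble = finetune_per_category(
        global_regressor,
        name_vectors[train_idx],
        scores[train_idx],
        pseudo_labels,
        config=cfg,
        min_finetune_items=min_finetune_items,
        seed=seed + 5,
    )
    return MintModels(
        embedding=embedding,
        cluster_model=cluster_model,
        pseudo_labels=pseudo_labels,
        predictor=predictor,
        stats=stats,
        global_regressor=global_regressor,
        ensemble=ensemble,
        name_vectors=name_vectors,
        scores=scores,
        train_idx=train_idx,
        test_idx=test_idx,
        variant=variant,
    )


def predict_heads(models: MintModels, X: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic point predictions of the three heads for vectors X."""
    probs = predict_category(models.predictor, X)
    hard = probs.argmax(axis=1)
    return {
        "fcwm": probs @ models.stats.means,
        "global": models.global_regressor.predict(X),
        "ensemble": models.ensemble.predict_routed(X, hard),
    }


def evaluate_heads(models: MintModels) -> dict[str, MetricReport]:
    """Held-out metric report per prediction head."""
    X = models.name_vectors[models.test_idx]
    y = models.scores[models.test_idx]
    preds = predict_heads(models, X)
    return {head: regression_metrics(y, p) for head, p in preds.items()}
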