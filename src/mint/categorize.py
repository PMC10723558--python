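"""Food-category pseudo-labels and the name-only category predictor.

Context embeddings (name + ingredients) are reduced to a low dimension
with UMAP and clustered with HDBSCAN; the clusters become category
pseudo-labels.  Soft memberships are derived from distances to the
cluster centroids in the reduced space (scikit-learn's HDBSCAN exposes
only a per-point own-cluster probability, not full membership vectors).
A five-layer network then learns to map name-only embeddings to the
soft memberships, so unseen items always get a category distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

from .errors import DimensionMismatchError, SingleCategoryError, TooFewPointsError
from .nn import MLP, MLPConfig

logger = logging.getLogger(__name__)

DEFAULT_REDUCER = {"n_components": 2, "n_neighbors": 50, "min_dist": 0.99}
DEFAULT_CLUSTERER = {
    "min_samples": 10,
    "min_cluster_size": None,  # None -> scaled to data size
    "cluster_selection_epsilon": 0.0,
}


def scaled_min_cluster_size(n_points: int) -> int:
    """min_cluster_size of 1000 at ~80K points, scaled down proportionally."""
    return max(10, int(round(0.0125 * n_points)))


@dataclass
class PseudoLabel:
    membership: np.ndarray
    hard_label: int
    is_noise: bool


@dataclass
class ClusterModel:
    reducer_params: dict
    clusterer_params: dict
    seed: int
    n_clusters: int
    centroids: np.ndarray       # (n_clusters, target_dim) in reduced space
    scale: float                # softmax temperature for memberships
    reduced: np.ndarray | None = field(default=None, repr=False)


def _memberships(reduced: np.ndarray, centroids: np.ndarray, scale: float):
    d = np.linalg.norm(reduced[:, None, :] - centroids[None, :, :], axis=2)
    logits = -d / max(scale, 1e-9)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def fit_pseudo_labels(
    context_vectors: np.ndarray,
    reducer_params: dict | None = None,
    clusterer_params: dict | None = None,
    seed: int = 0,
) -> tuple[ClusterModel, list[PseudoLabel]]:
    """Reduce, cluster, and derive soft category memberships.

    Every point gets a membership vector over the discovered clusters;
    points HDBSCAN leaves unassigned are flagged as noise but still get a
    distance-based membership.  Deterministic under a fixed seed.
    If the clusterer finds no cluster at all (e.g. all points identical),
    the whole dataset is treated as a single cluster.
    """
    X = np.asarray(context_vectors, dtype=float)
    rp = {**DEFAULT_REDUCER, **(reducer_params or {})}
    cp = {**DEFAULT_CLUSTERER, **(clusterer_params or {})}
    if cp.get("min_cluster_size") is None:
        cp["min_cluster_size"] = scaled_min_cluster_size(len(X))
    if len(X) < 2 * cp["min_cluster_size"]:
        raise TooFewPointsError(
            f"need >= {2 * cp['min_cluster_size']} points, got {len(X)}"
        )

    if X.shape[1] > rp["n_components"] and np.std(X) > 1e-12:
        import umap  # deferred: numba JIT import is slow

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(random_state=seed, **rp)
            reduced = np.asarray(reducer.fit_transform(X), dtype=float)
    else:
        # already low-dimensional or degenerate; cluster the raw points
        reduced = X.copy()

    def _cluster(eps: float) -> np.ndarray:
        clusterer = HDBSCAN(
            min_cluster_size=int(cp["min_cluster_size"]),
            min_samples=int(cp["min_samples"]),
            cluster_selection_epsilon=float(eps),
        )
        return clusterer.fit_predict(reduced)

    try:
        labels = _cluster(cp["cluster_selection_epsilon"])
    except TypeError:
        # scikit-learn's epsilon search can fail on some condensed trees;
        # fall back to plain cluster selection
        logger.warning(
            "cluster_selection_epsilon=%s failed in HDBSCAN; retrying with 0",
            cp["cluster_selection_epsilon"],
        )
        labels = _cluster(0.0)
    cluster_ids = sorted(set(labels) - {-1})
    if not cluster_ids:
        logger.info("no clusters found; treating the dataset as one cluster")
        labels = np.zeros(len(X), dtype=int)
        cluster_ids = [0]
    n_clusters = len(cluster_ids)

    centroids = np.vstack(
        [reduced[labels == cid].mean(axis=0) for cid in cluster_ids]
    )
    own = np.array(
        [
            np.linalg.norm(reduced[i] - centroids[cluster_ids.index(l)])
            for i, l in enumerate(labels)
            if l != -1
        ]
    )
    scale = float(np.median(own)) if len(own) else 1.0
    scale = max(scale, 1e-6)

    member = _memberships(reduced, centroids, scale)
    pseudo = [
        PseudoLabel(
            membership=member[i],
            hard_label=int(np.argmax(member[i])),
            is_noise=bool(labels[i] == -1),
        )
        for i in range(len(X))
    ]
    model = ClusterModel(
        reducer_params=rp,
        clusterer_params=cp,
        seed=seed,
        n_clusters=n_clusters,
        centroids=centroids,
        scale=scale,
        reduced=reduced,
    )
    n_noise = int(np.sum(labels == -1))
    logger.info(
        "pseudo-labels: %d clusters, %d/%d noise points", n_clusters, n_noise, len(X)
    )
    return model, pseudo


@dataclass
class CategoryPredictor:
    """Name-embedding -> category-probability network."""

    net: MLP
    n_categories: int
    input_dim: int
    loss_mode: str = "softmax_ce"


def train_category_predictor(
    name_vectors: np.ndarray,
    pseudo_labels: list[PseudoLabel],
    config: MLPConfig | None = None,
    seed: int = 0,
    loss_mode: str = "softmax_ce",
) -> CategoryPredictor:
    """Fit the five-layer category network on soft pseudo-label targets.

    Noise-flagged items are excluded from training.  ``loss_mode`` picks
    softmax + cross-entropy against the membership vector (default) or a
    per-class sigmoid + BCE multi-label variant.
    """
    X = np.asarray(name_vectors, dtype=float)
    keep = [i for i, p in enumerate(pseudo_labels) if not p.is_noise]
    if not keep:
        raise TooFewPointsError("all items are noise-flagged")
    Y = np.vstack([pseudo_labels[i].membership for i in keep])
    X = X[keep]
    n_categories = Y.shape[1]
    hard = Y.argmax(axis=1)
    if len(set(hard.tolist())) < 2:
        raise SingleCategoryError("training data covers a single category")
    if loss_mode not in ("softmax_ce", "bce"):
        raise ValueError(f"unknown loss_mode {loss_mode!r}")

    cfg = config or MLPConfig()
    net = MLP(
        input_dim=X.shape[1],
        output_dim=n_categories,
        task=loss_mode,
        config=cfg,
        seed=seed,
    )
    net.fit(X, Y)
    logger.info(
        "category predictor trained: %d items, %d categories, final val loss %s",
        len(X),
        n_categories,
        net.history["val_loss"][-1] if net.history["val_loss"] else "n/a",
    )
    return CategoryPredictor(
        net=net, n_categories=n_categories, input_dim=X.shape[1],
        loss_mode=loss_mode,
    )


def predict_category(
    predictor: CategoryPredictor, name_vectors: np.ndarray
) -> np.ndarray:
    """Probability vectors over categories; rows sum to 1."""
    X = np.atleast_2d(np.asarray(name_vectors, dtype=float))
    if X.shape[1] != predictor.input_dim:
        raise DimensionMismatchError(
            f"expected dim {predictor.input_dim}, got {X.shape[1]}"
        )
    out = predictor.net.forward(X)
    if predictor.loss_mode == "bce":  # normalize sigmoid outputs to a distribution
        out = out / np.maximum(out.sum(axis=1, keepdims=True), 1e-12)
    return out
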