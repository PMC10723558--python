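"""Nutrient-density regressors: FCWM baseline, global net, routed ensemble.

The global five-layer regressor maps name embeddings to a density score.
Per-category copies are fine-tuned (weight decay 0.001, same learning
rate) on the items of each pseudo-label category and routed at inference
by the predicted category.  MC dropout — repeated stochastic forward
passes with dropout active — provides 95% intervals.  FCWM is the
closed-form baseline: category confidences dotted with per-category true
mean scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .categorize import CategoryPredictor, PseudoLabel, predict_category
from .embeddings import FoodEmbeddingModel, embed_name
from .errors import EmptyInputError, LengthMismatchError
from .nn import MLP, MLPConfig

logger = logging.getLogger(__name__)


@dataclass
class CategoryStats:
    """Per-category true mean score (TM) and item count."""

    means: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.means) != len(self.counts):
            raise LengthMismatchError("means and counts differ in length")
        if not np.all(np.isfinite(self.means)) or np.any(self.means < 0):
            raise ValueError("TM values must be finite and >= 0")
        if np.any(self.counts < 1):
            raise ValueError("category counts must be >= 1")

    @classmethod
    def from_labels(
        cls, scores: np.ndarray, hard_labels: np.ndarray, n_categories: int
    ) -> "CategoryStats":
        scores = np.asarray(scores, dtype=float)
        hard_labels = np.asarray(hard_labels, dtype=int)
        means = np.empty(n_categories)
        counts = np.empty(n_categories, dtype=int)
        for c in range(n_categories):
            mask = hard_labels == c
            if not mask.any():
                raise ValueError(f"category {c} has no items")
            means[c] = scores[mask].mean()
            counts[c] = int(mask.sum())
        return cls(means=means, counts=counts)


def fcwm_predict(category_probs: np.ndarray, stats: CategoryStats) -> float:
    """Weighted mean of per-category true means: ``sum_i p_i * TM_i``."""
    p = np.asarray(category_probs, dtype=float)
    if p.shape != stats.means.shape:
        raise LengthMismatchError(
            f"probability vector length {p.shape} != categories {stats.means.shape}"
        )
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    return float(p @ stats.means)


@dataclass
class GlobalRegressor:
    net: MLP
    variant: str = "rrr_macro"
    input_dim: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(X)[:, 0]


def train_global_regressor(
    name_vectors: np.ndarray,
    scores: np.ndarray,
    config: MLPConfig | None = None,
    seed: int = 0,
    variant: str = "rrr_macro",
    min_items: int = 50,
) -> GlobalRegressor:
    """Fit the five-layer score regressor (MSE, linear output)."""
    X = np.asarray(name_vectors, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(X) != len(y):
        raise LengthMismatchError("vectors and scores differ in length")
    if len(X) < min_items:
        raise EmptyInputError(f"need >= {min_items} training items, got {len(X)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("scores must be finite")
    cfg = config or MLPConfig()
    net = MLP(input_dim=X.shape[1], output_dim=1, task="mse", config=cfg, seed=seed)
    net.fit(X, y)
    return GlobalRegressor(net=net, variant=variant, input_dim=X.shape[1])


@dataclass
class FinetunedEnsemble:
    base: GlobalRegressor
    models: dict[int, MLP]       # category -> fine-tuned copy (or base copy)
    n_categories: int
    variant: str = "rrr_macro"
    fallback_categories: list[int] = field(default_factory=list)

    def model_for(self, category: int) -> MLP:
        return self.models.get(int(category), self.base.net)

    def predict_routed(
        self, X: np.ndarray, categories: np.ndarray
    ) -> np.ndarray:
        """Deterministic point predictions routed by hard category."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        categories = np.asarray(categories, dtype=int)
        out = np.empty(len(X))
        for c in np.unique(categories):
            mask = categories == c
            out[mask] = self.model_for(int(c)).forward(X[mask])[:, 0]
        return out

    def predict_mixture(
        self, X: np.ndarray, category_probs: np.ndarray
    ) -> np.ndarray:
        """Confidence-weighted mixture over the per-category models."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        P = np.atleast_2d(np.asarray(category_probs, dtype=float))
        per = np.column_stack(
            [self.model_for(c).forward(X)[:, 0] for c in range(self.n_categories)]
        )
        return np.sum(P * per, axis=1)


def finetune_per_category(
    base: GlobalRegressor,
    name_vectors: np.ndarray,
    scores: np.ndarray,
    pseudo_labels: list[PseudoLabel],
    config: MLPConfig | None = None,
    weight_decay: float = 1e-3,
    min_finetune_items: int = 20,
    epochs: int | None = None,
    seed: int = 0,
) -> FinetunedEnsemble:
    """Fine-tune one copy of the base regressor per category.

    Each copy starts from the base weights and trains only on that
    category's (non-noise) items with the stated weight decay and the
    base learning rate.  Categories with fewer than
    ``min_finetune_items`` items fall back to the base model.
    """
    X = np.asarray(name_vectors, dtype=float)
    y = np.asarray(scores, dtype=float)
    hard = np.array(
        [p.hard_label if not p.is_noise else -1 for p in pseudo_labels], dtype=int
    )
    n_categories = len(pseudo_labels[0].membership)
    models: dict[int, MLP] = {}
    fallbacks: list[int] = []
    for c in range(n_categories):
        mask = hard == c
        n_c = int(mask.sum())
        copy = base.net.copy()
        if n_c < min_finetune_items:
            logger.info(
                "category %d has %d items < %d; falling back to base model",
                c, n_c, min_finetune_items,
            )
            fallbacks.append(c)
        elif epochs != 0:
            copy.fit(
                X[mask],
                y[mask],
                epochs=epochs,
                weight_decay=weight_decay,
                refit_norm=False,  # keep the base input normalization
                rng=np.random.default_rng(seed + 7919 * (c + 1)),
            )
        models[c] = copy
    return FinetunedEnsemble(
        base=base,
        models=models,
        n_categories=n_categories,
        variant=base.variant,
        fallback_categories=fallbacks,
    )


@dataclass(frozen=True)
class PredictionResult:
    name: str
    point_estimate: float
    ci_low: float
    ci_high: float
    predicted_category: int
    category_confidence: float
    variant: str

    def __post_init__(self):
        for v in (self.point_estimate, self.ci_low, self.ci_high):
            if not np.isfinite(v):
                raise ValueError("prediction values must be finite")
        if not (self.ci_low <= self.point_estimate <= self.ci_high):
            raise ValueError("interval must contain the point estimate")


def mc_dropout_samples(
    net: MLP, x: np.ndarray, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_mc`` stochastic forward passes with dropout active."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.array([net.forward(x, dropout_rng=rng)[0, 0] for _ in range(n_mc)])


def predict_with_uncertainty(
    ensemble: FinetunedEnsemble,
    predictor: CategoryPredictor,
    model: FoodEmbeddingModel,
    name: str,
    n_mc: int = 100,
    seed: int = 0,
    ci_method: str = "percentile",
    routing: str = "argmax",
) -> PredictionResult:
    """Embed a name, route to its category's model, MC-dropout the score.

    Point estimate is the mean over passes; the 95% interval is the
    2.5/97.5 percentile of the passes (or mean ± 1.96·SD with
    ``ci_method='normal'``).  With dropout rate 0 every pass is
    identical and the interval has width 0.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    vec = embed_name(model, name)  # raises EmptyNameError on empty input
    probs = predict_category(predictor, vec)[0]
    category = int(np.argmax(probs))
    rng = np.random.default_rng(seed)

    if routing == "argmax":
        samples = mc_dropout_samples(ensemble.model_for(category), vec, n_mc, rng)
    elif routing == "mixture":
        per = np.array(
            [
                mc_dropout_samples(ensemble.model_for(c), vec, n_mc, rng)
                for c in range(ensemble.n_categories)
            ]
        )  # (n_categories, n_mc)
        samples = probs @ per
    else:
        raise ValueError(f"unknown routing {routing!r}")

    if np.ptp(samples) == 0.0:  # degenerate dropout: exact point, zero width
        point = float(samples[0])
        return PredictionResult(
            name=name,
            point_estimate=point,
            ci_low=point,
            ci_high=point,
            predicted_category=category,
            category_confidence=float(probs[category]),
            variant=ensemble.variant,
        )
    point = float(samples.mean())
    if ci_method == "percentile":
        lo, hi = np.percentile(samples, [2.5, 97.5])
    elif ci_method == "normal":
        sd = float(samples.std())
        lo, hi = point - 1.96 * sd, point + 1.96 * sd
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # the sample mean can fall just outside the percentile band for very
    # skewed draws; widen so the interval always contains the point
    lo, hi = min(float(lo), point), max(float(hi), point)
    return PredictionResult(
        name=name,
        point_estimate=point,
        ci_low=lo,
        ci_high=hi,
        predicted_category=category,
        category_confidence=float(probs[category]),
        variant=ensemble.variant,
    )
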