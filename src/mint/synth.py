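"""Seeded synthetic food items, recipe corpora and restaurant menus.

Items carry a latent category that controls the name vocabulary, the
ingredient pool and the nutrient distribution, so every downstream stage
(embedding, clustering, category prediction, score regression, menu
aggregation) can be exercised and checked against planted ground truth.

An optional per-word "health effect" makes the nutrient draw depend on the
exact words in the name (recommended amounts scaled up, restricted scaled
down, or vice versa).  With it enabled, a name-reading regressor can beat a
category-mean baseline — the structure the routed fine-tuned models are
designed to exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyVocabularyError
from .nutrients import (
    DEFAULT_DAILY_VALUES,
    MACRO_RECOMMENDED,
    NUTRIENTS,
    RECOMMENDED,
    NutrientProfile,
    compute_rrr_macro,
)

logger = logging.getLogger(__name__)

_FILLER_TEMPLATES = (
    "combine everything in a bowl and mix well",
    "cook over medium heat until done then serve warm",
    "season to taste and let rest before serving",
    "prepare the ingredients then bake until golden",
    "stir gently and chill before plating",
)

# Syllable pools used to mint category-specific pseudo-words.
_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu "
    "ka ke ki ko ku la le li lo lu ma me mi mo mu na ne ni no nu "
    "pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu "
    "va ve vi vo vu za ze zi zo zu"
).split()


@dataclass
class FoodItem:
    name: str
    ingredients: list[str]
    profile: NutrientProfile
    true_category: int


@dataclass
class SyntheticConfig:
    """Parameters for the synthetic generator.

    ``name_vocab`` and ``ingredient_pools`` hold one word list per
    category; ``nutrient_means`` one amount-per-nutrient mapping per
    category (canonical units).  ``nutrient_cv`` is the coefficient of
    variation of the multiplicative log-normal noise on every amount.
    """

    items_per_category: int
    name_vocab: list[list[str]]
    ingredient_pools: list[list[str]]
    nutrient_means: list[dict[str, float]]
    nutrient_cv: float = 0.15
    name_length_range: tuple[int, int] = (2, 4)
    word_effect_sd: float = 0.0
    seed: int = 0

    @property
    def n_categories(self) -> int:
        return len(self.name_vocab)

    def validate(self) -> None:
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        if not (
            len(self.ingredient_pools)
            == len(self.nutrient_means)
            == self.n_categories
        ):
            raise ValueError("per-category lists must have equal length")
        for vocab in list(self.name_vocab) + list(self.ingredient_pools):
            if len(vocab) == 0:
                raise EmptyVocabularyError("empty category vocabulary")
        for means in self.nutrient_means:
            if any(v <= 0 for v in means.values()):
                raise ValueError("nutrient means must be positive")
        if self.nutrient_cv < 0:
            raise ValueError("nutrient_cv must be >= 0")
        lo, hi = self.name_length_range
        if lo < 1 or hi < lo:
            raise ValueError("bad name_length_range")
        if self.items_per_category < 1:
            raise ValueError("items_per_category must be >= 1")


@dataclass
class SyntheticCorpus:
    items: list[FoodItem]
    config: SyntheticConfig
    documents: list[str] = field(default_factory=list)

    @property
    def n_categories(self) -> int:
        return self.config.n_categories

    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def true_categories(self) -> np.ndarray:
        return np.array([it.true_category for it in self.items], dtype=int)

    def rrr_macro(self) -> np.ndarray:
        return np.array(
            [compute_rrr_macro(it.profile).value for it in self.items]
        )

    def to_frame(self) -> pd.DataFrame:
        from .nutrients import CSV_COLUMNS

        rows = []
        for it in self.items:
            row = {"name": it.name, "true_category": it.true_category,
                   "ingredients": ";".join(it.ingredients)}
            for k, col in CSV_COLUMNS.items():
                row[col] = it.profile.amounts.get(k, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _word_effects(config: SyntheticConfig, rng: np.random.Generator):
    """Per-(category, word) effect table; deterministic in iteration order."""
    effects = []
    for vocab in config.name_vocab:
        effects.append(
            {w: rng.normal(0.0, config.word_effect_sd) for w in sorted(set(vocab))}
        )
    return effects


def generate_food_items(config: SyntheticConfig) -> SyntheticCorpus:
    """Draw ``n_categories * items_per_category`` items from the config.

    Nutrient amounts are log-normal around the category mean with the
    configured CV (mean-preserving parameterization).  Identical
    ``(config, seed)`` yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    effects = _word_effects(config, rng)
    sigma2 = np.log1p(config.nutrient_cv**2)
    sigma = np.sqrt(sigma2)
    lo, hi = config.name_length_range

    items: list[FoodItem] = []
    for cat in range(config.n_categories):
        vocab = list(config.name_vocab[cat])
        pool = list(config.ingredient_pools[cat])
        means = config.nutrient_means[cat]
        # first pass: names and their word-effect ratio multipliers, so the
        # multipliers can be normalized to mean 1 within the category (the
        # planted category-mean score stays recoverable)
        names, mults = [], []
        for _ in range(config.items_per_category):
            n_words = int(rng.integers(lo, hi + 1))
            replace = n_words > len(vocab)
            words = list(rng.choice(vocab, size=n_words, replace=replace))
            names.append(words)
            h = float(np.mean([effects[cat][w] for w in words]))
            mults.append(np.exp(2.0 * h))
        mults = np.asarray(mults)
        if config.word_effect_sd > 0:
            mults = mults / mults.mean()
        else:
            mults = np.ones_like(mults)
        for words, e in zip(names, mults):
            name = " ".join(words)
            n_ing = int(rng.integers(2, min(6, len(pool)) + 1))
            ingredients = list(rng.choice(pool, size=n_ing, replace=False))
            amounts = {}
            root = np.sqrt(e)
            for k in NUTRIENTS:
                m = means[k]
                if config.nutrient_cv > 0:
                    x = m * np.exp(rng.normal(-sigma2 / 2.0, sigma))
                else:
                    x = m
                x *= root if k in RECOMMENDED else 1.0 / root
                amounts[k] = float(x)
            items.append(FoodItem(name, ingredients, NutrientProfile(amounts), cat))
    return SyntheticCorpus(items=items, config=config)


def generate_recipe_corpus(
    corpus: SyntheticCorpus, include_filler: bool = True
) -> list[str]:
    """One recipe-style document per item: name, ingredients, filler.

    Stores the documents on the corpus and returns them; logs the total
    token count.
    """
    if not corpus.items:
        raise EmptyVocabularyError("corpus has no items")
    rng = np.random.default_rng(corpus.config.seed + 104729)
    docs = []
    for it in corpus.items:
        parts = [it.name, " ".join(it.ingredients)]
        if include_filler:
            parts.append(_FILLER_TEMPLATES[int(rng.integers(len(_FILLER_TEMPLATES)))])
        docs.append(" ".join(p for p in parts if p))
    n_tokens = sum(len(d.split()) for d in docs)
    logger.info("recipe corpus: %d documents, %d tokens", len(docs), n_tokens)
    corpus.documents = docs
    return docs


def generate_restaurants(
    corpus: SyntheticCorpus,
    n_restaurants: int,
    menu_size_range: tuple[int, int],
    category_mix: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample restaurant menus from the item pool.

    ``category_mix`` is either a single weight vector shared by all
    restaurants or an ``(n_restaurants, n_categories)`` array; each row
    must sum to 1.  Returns a table with columns ``restaurant_id,
    item_name, true_category, rrr_macro``.
    """
    lo, hi = menu_size_range
    if lo < 1 or hi < lo:
        raise ValueError("menu_size_range min must be >= 1 and <= max")
    mix = np.atleast_2d(np.asarray(category_mix, dtype=float))
    if mix.shape[0] == 1:
        mix = np.repeat(mix, n_restaurants, axis=0)
    if mix.shape != (n_restaurants, corpus.n_categories):
        raise ValueError("category_mix shape mismatch")
    if not np.allclose(mix.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each restaurant's category mix must sum to 1")

    rng = np.random.default_rng(seed)
    by_cat = [
        [i for i, it in enumerate(corpus.items) if it.true_category == c]
        for c in range(corpus.n_categories)
    ]
    scores = corpus.rrr_macro()
    rows = []
    for r in range(n_restaurants):
        size = int(rng.integers(lo, hi + 1))
        cats = rng.choice(corpus.n_categories, size=size, p=mix[r])
        for c in cats:
            idx = int(rng.choice(by_cat[int(c)]))
            it = corpus.items[idx]
            rows.append(
                {
                    "restaurant_id": f"R{r:03d}",
                    "item_name": it.name,
                    "true_category": it.true_category,
                    "rrr_macro": float(scores[idx]),
                }
            )
    return pd.DataFrame(rows)


def _mint_words(rng: np.random.Generator, syllables: list[str], n: int) -> list[str]:
    words = set()
    while len(words) < n:
        k = int(rng.integers(2, 4))
        words.add("".join(rng.choice(syllables, size=k)))
    return sorted(words)


def macro_targeted_means(target_rrr_macro: float) -> dict[str, float]:
    """Category nutrient means whose exact profile scores the target.

    Restricted nutrients sit at 100 %DV; protein/fiber (and the
    micronutrients, so plain RRR matches too) at ``100 * target`` %DV.
    """
    means = {}
    for k in NUTRIENTS:
        dv = DEFAULT_DAILY_VALUES[k]
        means[k] = dv if k not in RECOMMENDED else dv * target_rrr_macro
    return means


def make_benchmark_config(
    seed: int = 0,
    items_per_category: int = 500,
    target_rrr_macro: tuple[float, ...] = (0.3, 0.7, 1.1, 1.5),
    nutrient_cv: float = 0.15,
    word_effect_sd: float = 0.25,
    vocab_size: int = 14,
    pool_size: int = 10,
    overlap: float = 0.1,
    name_length_range: tuple[int, int] = (2, 4),
) -> SyntheticConfig:
    """Default synthetic benchmark: one category per target score.

    Category vocabularies are minted from disjoint syllable pools (so
    names are separable and subwords carry category signal), with an
    ``overlap`` fraction of words shared across categories to mimic
    ambiguous names.
    """
    n_categories = len(target_rrr_macro)
    rng = np.random.default_rng(seed)
    syl = list(_SYLLABLES)
    rng.shuffle(syl)
    per = len(syl) // n_categories
    vocabs, pools = [], []
    for c in range(n_categories):
        chunk = syl[c * per : (c + 1) * per]
        vocabs.append(_mint_words(rng, chunk, vocab_size))
        pools.append(_mint_words(rng, chunk, pool_size))
    if overlap > 0:
        n_shared = max(1, int(round(overlap * vocab_size)))
        for c in range(n_categories):
            other = (c + 1) % n_categories
            shared = list(rng.choice(vocabs[other], size=n_shared, replace=False))
            vocabs[c] = sorted(set(vocabs[c]) | set(shared))
    return SyntheticConfig(
        items_per_category=items_per_category,
        name_vocab=vocabs,
        ingredient_pools=pools,
        nutrient_means=[macro_targeted_means(t) for t in target_rrr_macro],
        nutrient_cv=nutrient_cv,
        name_length_range=name_length_range,
        word_effect_sd=word_effect_sd,
        seed=seed,
    )


def make_benchmark(seed: int = 0, **kwargs) -> SyntheticCorpus:
    """Benchmark corpus with documents attached."""
    corpus = generate_food_items(make_benchmark_config(seed=seed, **kwargs))
    generate_recipe_corpus(corpus)
    return corpus
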