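# mint

Predict the nutrient density of food items **from their names alone**, and
aggregate item predictions into restaurant-level healthfulness scores.

The pipeline:

1. **Nutrient scoring** — `RRR` (ratio of recommended to restricted
   nutrients, mean %DV over mean %DV) and its macro-only variant
   `RRRmacro` (protein + fiber numerator), using FDA daily values.
   Both are portion-size invariant by construction.
2. **Food-language embeddings** — a subword-aware skip-gram model trained
   on a recipe-style corpus (name + ingredients + instructions); item
   names are embedded by averaging word vectors, unseen words compose
   from hashed character n-grams.
3. **Category pseudo-labels** — ingredient-contextualized sentences
   (`"<name> made with <ing1>, <ing2>, …"`) are embedded, reduced to 2-D
   with UMAP and soft-clustered with HDBSCAN; a five-layer network learns
   to predict the category distribution from the name embedding alone.
4. **Score prediction** — a five-layer regressor (MSE, linear output) is
   trained globally, then fine-tuned per category (weight decay 1e-3);
   inference routes each name through its predicted category's model.
   MC dropout (100 stochastic passes) yields 95% confidence intervals.
   A closed-form baseline, the category-weighted mean `Σ pᵢ·TMᵢ`, is
   included for ablations.
5. **Restaurant aggregation** — `RND` = median menu `RRRmacro`, with
   optional histogram-based outlier filtering (3% contamination default)
   and per-region means.

A fully seeded synthetic-data generator (`mint.synth`) plants latent
categories, vocabularies, ingredient pools and nutrient distributions so
that every stage is testable offline with recoverable ground truth.

## CLI

```bash
mint synth --config synth.yaml --out data/        # items.csv, corpus.txt, menus.csv
mint score data/items.csv scored.csv --variant rrr-macro
mint train-embeddings data/corpus.txt --dim 300 --epochs 5 --seed 7 --out model.npz
mint run --config pipeline.yaml                   # full pipeline + manifest
mint predict data/menus.csv --checkpoints out/checkpoints --out preds.csv
mint rnd data/menus.csv --regions regions.csv --out-dir out/
mint evaluate preds.csv truth.csv
mint ablation --config ablation.yaml              # FCWM vs global vs ensemble
```

Example pipeline config (`pipeline.yaml`; unknown keys are rejected):

```yaml
items: data/items.csv      # name + nutrient columns (+ optional ingredients)
corpus: data/corpus.txt    # one document per line
menus: data/menus.csv      # restaurant_id, item_name
out: out/
variant: rrr_macro
seed: 7
embed_dim: 300
```

Synthetic config (`synth.yaml`):

```yaml
benchmark: {seed: 0, items_per_category: 500}
restaurants: {n_restaurants: 20, menu_size_range: [10, 30]}
```

## Layout

```
src/mint/
  nutrients.py    %DV, RRR, RRRmacro, daily-value table, CSV scoring
  synth.py        seeded synthetic items / corpora / menus
  embeddings.py   skip-gram + subword embeddings, context sentences, encoders
  categorize.py   UMAP + HDBSCAN pseudo-labels, category predictor
  nn.py           five-layer MLP (Adam, dropout, early stopping, MC dropout)
  regression.py   FCWM, global regressor, per-category fine-tuned ensemble
  aggregate.py    HBOS outlier filter, RND, region means
  evaluate.py     R²/RMSE/MAE/match-rate, ablation harness
  workflow.py     in-memory end-to-end fitting (shared by tests/CLI)
  pipeline.py     file-based pipeline, checkpoints, run manifest
  tables.py       CSV/JSON readers-writers with row-error reporting
  config.py       schema-validated YAML pipeline config
  cli.py          `mint` command group
```
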