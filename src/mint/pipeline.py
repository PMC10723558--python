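"""File-based end-to-end pipeline with versioned artifacts and a manifest.

Stage order: embeddings -> pseudo-labels -> category predictor -> global
regressor -> per-category fine-tuning -> menu predictions -> RND.  Each
stage's failure is wrapped in a :class:`~mint.errors.StageError` naming
the stage; artifacts written before the failure are kept on disk.

A single global seed fans out to per-stage derived seeds (seed + stage
index), so individual stages can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from .categorize import (
    CategoryPredictor,
    fit_pseudo_labels,
    predict_category,
    train_category_predictor,
)
from .config import PipelineConfig
from .embeddings import (
    FoodEmbeddingModel,
    WordAverageEncoder,
    build_context_sentence,
    embed_context,
    embed_names,
    train_embedding_model,
)
from .errors import StageError
from .nn import MLP, MLPConfig
from .nutrients import score_frame
from .regression import (
    CategoryStats,
    FinetunedEnsemble,
    GlobalRegressor,
    finetune_per_category,
    predict_with_uncertainty,
    train_global_regressor,
)
from .tables import read_items, read_menus, read_region_map, write_predictions

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fnv(s: str) -> int:
    h = 0xCBF29CE484222325
    for b in s.encode("utf-8"):
        h = ((h ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def save_checkpoint(
    out_dir: Path,
    embedding: FoodEmbeddingModel,
    predictor: CategoryPredictor,
    stats: CategoryStats,
    base: GlobalRegressor,
    ensemble: FinetunedEnsemble,
    config: PipelineConfig,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    embedding.save(str(out_dir / "embedding.npz"))
    np.savez(out_dir / "category_predictor.npz", **predictor.net.state_arrays())
    np.savez(out_dir / "regressor_base.npz", **base.net.state_arrays())
    for c, net in ensemble.models.items():
        np.savez(out_dir / f"regressor_cat{c}.npz", **net.state_arrays())
    manifest = {
        "variant": config.variant,
        "n_categories": predictor.n_categories,
        "embedding_dim": embedding.dimension,
        "category_means": stats.means.tolist(),
        "category_counts": stats.counts.tolist(),
        "fallback_categories": ensemble.fallback_categories,
        "seed": config.seed,
        "mlp": config.mlp_config().__dict__,
    }
    (out_dir / "checkpoint.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )


def load_checkpoint(out_dir: Path):
    manifest = json.loads((out_dir / "checkpoint.json").read_text(encoding="utf-8"))
    cfg = MLPConfig(**manifest["mlp"])
    dim = manifest["embedding_dim"]
    n_cat = manifest["n_categories"]
    embedding = FoodEmbeddingModel.load(str(out_dir / "embedding.npz"))

    def load_net(path: Path, output_dim: int, task: str) -> MLP:
        net = MLP(input_dim=dim, output_dim=output_dim, task=task, config=cfg)
        with np.load(path) as z:
            net.load_state_arrays({k: z[k] for k in z.files})
        return net

    predictor = CategoryPredictor(
        net=load_net(out_dir / "category_predictor.npz", n_cat, "softmax_ce"),
        n_categories=n_cat,
        input_dim=dim,
    )
    base = GlobalRegressor(
        net=load_net(out_dir / "regressor_base.npz", 1, "mse"),
        variant=manifest["variant"],
        input_dim=dim,
    )
    models = {
        c: load_net(out_dir / f"regressor_cat{c}.npz", 1, "mse")
        for c in range(n_cat)
        if (out_dir / f"regressor_cat{c}.npz").exists()
    }
    ensemble = FinetunedEnsemble(
        base=base,
        models=models,
        n_categories=n_cat,
        variant=manifest["variant"],
        fallback_categories=manifest.get("fallback_categories", []),
    )
    stats = CategoryStats(
        means=np.array(manifest["category_means"]),
        counts=np.array(manifest["category_counts"]),
    )
    return embedding, predictor, stats, ensemble, manifest


def predict_menu_items(
    embedding: FoodEmbeddingModel,
    predictor: CategoryPredictor,
    ensemble: FinetunedEnsemble,
    names: list[str],
    n_mc: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each unique name once; seeds derive from the name itself, so
    the result does not depend on menu order."""
    rows = {}
    for name in names:
        if name in rows:
            continue
        res = predict_with_uncertainty(
            ensemble,
            predictor,
            embedding,
            name,
            n_mc=n_mc,
            seed=(seed + _fnv(name)) % (2**32),
        )
        rows[name] = {
            "name": name,
            "predicted_category": res.predicted_category,
            "score": res.point_estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
        }
    return pd.DataFrame([rows[n] for n in sorted(rows)])


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the artifact directory."""
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "stage_seconds": {},
        "input_checksums": {},
        "derived_seeds": {},
    }
    timings = manifest["stage_seconds"]

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Ctx()

    seeds = {s: config.seed + i for i, s in enumerate(
        ["embeddings", "pseudo_labels", "category_predictor", "global", "finetune",
         "predict"], start=1)}
    manifest["derived_seeds"] = seeds

    with stage("load_inputs"):
        items_path = Path(config.items)
        corpus_path = Path(config.corpus)
        manifest["input_checksums"][str(items_path)] = _sha256(items_path)
        manifest["input_checksums"][str(corpus_path)] = _sha256(corpus_path)
        items, row_errors = read_items(items_path)
        if row_errors:
            logger.warning("%d malformed item rows skipped", len(row_errors))
            (out_dir / "row_errors.json").write_text(
                json.dumps([e.__dict__ for e in row_errors], indent=2),
                encoding="utf-8",
            )
        documents = [
            line for line in corpus_path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        scores = score_frame(items, variant=config.variant, missing=config.missing)

    with stage("train_embeddings"):
        embedding = train_embedding_model(
            documents,
            dimension=config.embed_dim,
            epochs=config.embed_epochs,
            seed=seeds["embeddings"],
        )
        embedding.save(str(out_dir / "embedding.npz"))
        embedding.export_word_vectors(str(out_dir / "word_vectors.txt"))
        name_vectors = embed_names(embedding, list(items["name"]))

    with stage("pseudo_labels"):
        encoder = WordAverageEncoder(embedding)
        ingredients = (
            items["ingredients"].fillna("") if "ingredients" in items.columns
            else pd.Series([""] * len(items))
        )
        context_vectors = np.vstack(
            [
                embed_context(
                    encoder,
                    build_context_sentence(
                        n, [w for w in ing.split(";") if w]
                    ),
                )
                for n, ing in zip(items["name"], ingredients)
            ]
        )
        cluster_model, pseudo_labels = fit_pseudo_labels(
            context_vectors,
            reducer_params=config.reducer_params,
            clusterer_params=config.clusterer_params,
            seed=seeds["pseudo_labels"],
        )
        plab = pd.DataFrame(
            {
                "item_id": range(len(pseudo_labels)),
                "hard_label": [p.hard_label for p in pseudo_labels],
                "is_noise": [p.is_noise for p in pseudo_labels],
            }
        )
        for k in range(cluster_model.n_clusters):
            plab[f"p_{k}"] = [float(p.membership[k]) for p in pseudo_labels]
        plab.to_csv(out_dir / "pseudo_labels.csv", index=False,
                    float_format="%.10g")

    mlp_cfg = config.mlp_config()
    with stage("category_predictor"):
        predictor = train_category_predictor(
            name_vectors, pseudo_labels, config=mlp_cfg,
            seed=seeds["category_predictor"],
        )

    with stage("global_regressor"):
        base = train_global_regressor(
            name_vectors,
            scores.to_numpy(),
            config=mlp_cfg,
            seed=seeds["global"],
            variant=config.variant,
        )

    with stage("finetune"):
        ensemble = finetune_per_category(
            base,
            name_vectors,
            scores.to_numpy(),
            pseudo_labels,
            config=mlp_cfg,
            weight_decay=config.finetune_weight_decay,
            min_finetune_items=config.min_finetune_items,
            seed=seeds["finetune"],
        )
        hard = np.array(
            [p.hard_label for p in pseudo_labels if not p.is_noise], dtype=int
        )
        keep = np.array([not p.is_noise for p in pseudo_labels])
        stats = CategoryStats.from_labels(
            scores.to_numpy()[keep], hard, cluster_model.n_clusters
        )
        save_checkpoint(out_dir / "checkpoints", embedding, predictor, stats,
                        base, ensemble, config)

    if config.menus:
        with stage("predict"):
            manifest["input_checksums"][config.menus] = _sha256(Path(config.menus))
            menus = read_menus(config.menus)
            preds = predict_menu_items(
                embedding,
                predictor,
                ensemble,
                list(menus["item_name"]),
                n_mc=config.n_mc,
                seed=seeds["predict"],
            )
            write_predictions(preds, out_dir / "predictions.csv")

        with stage("rnd"):
            merged = menus.merge(
                preds[["name", "score"]], left_on="item_name", right_on="name",
                how="left",
            )
            region_map = (
                read_region_map(config.regions) if config.regions else None
            )
            menu_objs = agg.menus_from_frame(
                merged.rename(columns={"score": "pred_score"}),
                score_column="pred_score",
                region_map=region_map,
            )
            rnds = [
                agg.compute_rnd(
                    m,
                    apply_filter=config.apply_outlier_filter,
                    contamination=config.contamination,
                )
                for m in menu_objs
            ]
            pd.DataFrame(
                [
                    {
                        "restaurant_id": r.restaurant_id,
                        "rnd": r.value,
                        "n_items": r.n_items,
                        "n_removed": r.n_removed,
                    }
                    for r in rnds
                ]
            ).to_csv(out_dir / "rnd.csv", index=False, float_format="%.10g")
            if region_map:
                summaries, unmapped = agg.aggregate_by_region(rnds)
                pd.DataFrame(
                    [
                        {
                            "region": s.region,
                            "mean_rnd": s.mean_rnd,
                            "n_restaurants": s.n_restaurants,
                        }
                        for s in summaries
                    ]
                ).to_csv(out_dir / "regions.csv", index=False,
                         float_format="%.10g")
                if unmapped:
                    logger.warning("%d restaurants had no region", len(unmapped))

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out_dir
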