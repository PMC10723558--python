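"""Regression metrics and the ablation harness over prediction heads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, LengthMismatchError, ZeroVarianceError


@dataclass(frozen=True)
class MetricReport:
    r_squared: float
    rmse: float
    mae: float
    match_rate: float
    n: int


def regression_metrics(y_true, y_pred) -> MetricReport:
    """R² (1 − SS_res/SS_tot, may be negative), RMSE, MAE, match rate.

    NaN predictions count as unmatched and are excluded from the error
    metrics; ``match_rate`` is the matched fraction.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise LengthMismatchError(f"shapes differ: {yt.shape} vs {yp.shape}")
    n = yt.size
    if n == 0:
        raise EmptyInputError("no observations")
    matched = np.isfinite(yp)
    yt_m, yp_m = yt[matched], yp[matched]
    if yt_m.size == 0:
        raise EmptyInputError("no matched predictions")
    ss_tot = float(np.sum((yt_m - yt_m.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroVarianceError("y_true has zero variance; R^2 undefined")
    ss_res = float(np.sum((yt_m - yp_m) ** 2))
    return MetricReport(
        r_squared=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(np.mean((yt_m - yp_m) ** 2))),
        mae=float(np.mean(np.abs(yt_m - yp_m))),
        match_rate=float(matched.sum() / n),
        n=int(n),
    )


@dataclass
class AblationResult:
    """Per-config per-seed metric reports plus mean ± SD summaries."""

    reports: dict[tuple[str, str], list[MetricReport]]

    def summary(self) -> dict[tuple[str, str], dict[str, tuple[float, float]]]:
        out = {}
        for key, reps in self.reports.items():
            out[key] = {
                m: (
                    float(np.mean([getattr(r, m) for r in reps])),
                    float(np.std([getattr(r, m) for r in reps])) if len(reps) > 1 else 0.0,
                )
                for m in ("r_squared", "rmse", "mae")
            }
        return out

    def to_markdown(self) -> str:
        lines = ["| backend | head | R2 | RMSE | MAE |", "|---|---|---|---|---|"]
        for (backend, head), stats in self.summary().items():
            cells = [
                f"{stats[m][0]:.3f} ± {stats[m][1]:.3f}"
                for m in ("r_squared", "rmse", "mae")
            ]
            lines.append(f"| {backend} | {head} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def run_ablation(
    corpus,
    configs: list[tuple[str, str]],
    n_seeds: int = 5,
    base_seed: int = 0,
    variant: str = "rrr_macro",
    **fit_kwargs,
) -> AblationResult:
    """Train and evaluate each (embedding backend, head) config per seed.

    Heads: ``fcwm`` | ``global`` | ``ensemble``.  All heads of one
    backend/seed share a fitted pipeline (80/20 train/test split,
    stratified by planted category), so the comparison isolates the
    prediction head exactly.
    """
    from .workflow import evaluate_heads, fit_mint

    if len(configs) < 2:
        raise ValueError("need at least 2 configs to ablate")
    for backend, head in configs:
        if head not in ("fcwm", "global", "ensemble"):
            raise ValueError(f"unknown head {head!r}")

    reports: dict[tuple[str, str], list[MetricReport]] = {c: [] for c in configs}
    for s in range(n_seeds):
        seed = base_seed + s
        cache: dict[str, dict[str, MetricReport]] = {}
        for backend, head in configs:
            if backend not in cache:
                models = fit_mint(corpus, seed=seed, variant=variant, **fit_kwargs)
                cache[backend] = evaluate_heads(models)
            reports[(backend, head)].append(cache[backend][head])
    return AblationResult(reports=reports)
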