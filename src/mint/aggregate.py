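"""Restaurant-level aggregation: outlier filtering, RND, region means.

RND (restaurant nutrient density) is the median of a menu's per-item
macro density scores.  Before aggregation, extreme item scores can be
removed with a histogram-based outlier score: equal-width bins, score =
negative log of the bin's relative frequency, drop the top fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError

#: fraction of items removed in the reference data (762 / 24748 ~ 3%)
DEFAULT_CONTAMINATION = 0.03


@dataclass
class RestaurantMenu:
    restaurant_id: str
    item_names: list[str]
    scores: np.ndarray
    region: str | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) == 0:
            raise EmptyInputError("menu has no items")
        if len(self.item_names) != len(self.scores):
            raise ValueError("names and scores differ in length")


@dataclass(frozen=True)
class RNDScore:
    restaurant_id: str
    value: float
    n_items: int
    n_removed: int
    region: str | None = None


@dataclass(frozen=True)
class RegionSummary:
    region: str
    mean_rnd: float
    n_restaurants: int


def hbos_scores(scores: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Histogram-based outlier score: ``-log`` relative bin frequency.

    Equal-width bins over the data range; bin count defaults to
    ``round(sqrt(n))``.  Higher score = rarer bin = more outlying.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n == 0:
        raise EmptyInputError("no scores")
    if n_bins is None:
        n_bins = max(1, int(round(np.sqrt(n))))
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:  # all identical: nothing is outlying
        return np.zeros(n)
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    rel = counts[idx] / n
    return -np.log(rel)


def filter_outliers(
    scores: np.ndarray,
    contamination: float = DEFAULT_CONTAMINATION,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the ``contamination`` fraction of points with highest HBOS.

    Returns ``(kept_scores, removed_indices)``; the two partition the
    input.  Ties are broken by original index (stable), so the result is
    deterministic.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) == 0:
        raise EmptyInputError("no scores to filter")
    if not (0.0 <= contamination < 0.5):
        raise ValueError("contamination must be in [0, 0.5)")
    n_remove = int(np.floor(contamination * len(x) + 1e-9))
    if n_remove == 0:
        return x.copy(), np.array([], dtype=int)
    s = hbos_scores(x, n_bins=n_bins)
    order = np.lexsort((np.arange(len(x)), -s))  # by score desc, then index
    removed = np.sort(order[:n_remove])
    keep_mask = np.ones(len(x), dtype=bool)
    keep_mask[removed] = False
    return x[keep_mask], removed


def compute_rnd(
    menu: RestaurantMenu,
    apply_filter: bool = False,
    contamination: float = DEFAULT_CONTAMINATION,
) -> RNDScore:
    """Median of the menu's surviving item scores.

    Even-length menus use the midpoint of the two middle order
    statistics.
    """
    scores = menu.scores
    n_removed = 0
    if apply_filter:
        kept, removed = filter_outliers(scores, contamination=contamination)
        n_removed = len(removed)
        scores = kept
    if len(scores) == 0:
        raise EmptyInputError(
            f"restaurant {menu.restaurant_id}: all items removed as outliers"
        )
    return RNDScore(
        restaurant_id=menu.restaurant_id,
        value=float(np.median(scores)),
        n_items=len(scores),
        n_removed=n_removed,
        region=menu.region,
    )


def aggregate_by_region(
    rnd_scores: list[RNDScore],
    region_map: dict[str, str] | None = None,
) -> tuple[list[RegionSummary], list[RNDScore]]:
    """Arithmetic mean RND per region; unmapped restaurants returned apart."""
    by_region: dict[str, list[float]] = {}
    unmapped: list[RNDScore] = []
    for r in rnd_scores:
        region = r.region
        if region_map is not None and r.restaurant_id in region_map:
            region = region_map[r.restaurant_id]
        if region is None:
            unmapped.append(r)
            continue
        by_region.setdefault(region, []).append(r.value)
    summaries = [
        RegionSummary(region=k, mean_rnd=float(np.mean(v)), n_restaurants=len(v))
        for k, v in sorted(by_region.items())
    ]
    return summaries, unmapped


def menus_from_frame(
    frame: pd.DataFrame,
    score_column: str = "rrr_macro",
    region_map: dict[str, str] | None = None,
) -> list[RestaurantMenu]:
    """Group a ``restaurant_id, item_name, <score>`` table into menus."""
    menus = []
    for rid, grp in frame.groupby("restaurant_id", sort=True):
        menus.append(
            RestaurantMenu(
                restaurant_id=str(rid),
                item_names=list(grp["item_name"]),
                scores=grp[score_column].to_numpy(dtype=float),
                region=region_map.get(str(rid)) if region_map else None,
            )
        )
    return menus
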