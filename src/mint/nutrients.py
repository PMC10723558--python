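"""Nutrient-density scoring: %DV, RRR and its macro-only variant.

RRR is the mean percent-daily-value of the six recommended nutrients
(protein, fiber, vitamin A, vitamin C, calcium, iron) divided by the mean
percent-daily-value of the five restricted nutrients (calories, total
sugar, cholesterol, saturated fat, sodium).  The macro variant keeps only
protein and fiber in the numerator.  Both scores are ratios of means, so
they are invariant to portion size (multiplying every amount by c > 0
leaves the score unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    MissingNutrientError,
    NegativeAmountError,
    UndefinedDenominatorError,
    UnknownNutrientError,
)

#: Canonical nutrient keys, in a fixed order.
RECOMMENDED = ("protein", "fiber", "vitamin_a", "vitamin_c", "calcium", "iron")
RESTRICTED = ("calories", "total_sugar", "cholesterol", "saturated_fat", "sodium")
MACRO_RECOMMENDED = ("protein", "fiber")
NUTRIENTS = RECOMMENDED + RESTRICTED

#: FDA daily values, in the units of the canonical table
#: (g, g, µg, mg, mg, mg, kcal, g, mg, g, mg respectively).
DEFAULT_DAILY_VALUES: dict[str, float] = {
    "protein": 50.0,       # g
    "fiber": 28.0,         # g
    "vitamin_a": 900.0,    # µg
    "vitamin_c": 90.0,     # mg
    "calcium": 1300.0,     # mg
    "iron": 18.0,          # mg
    "calories": 2000.0,    # kcal
    "total_sugar": 50.0,   # g
    "cholesterol": 300.0,  # mg
    "saturated_fat": 20.0, # g
    "sodium": 2300.0,      # mg
}

#: CSV column name for each nutrient (units encoded in the suffix).
CSV_COLUMNS: dict[str, str] = {
    "protein": "protein_g",
    "fiber": "fiber_g",
    "vitamin_a": "vitamin_a_ug",
    "vitamin_c": "vitamin_c_mg",
    "calcium": "calcium_mg",
    "iron": "iron_mg",
    "calories": "calories_kcal",
    "total_sugar": "sugar_g",
    "cholesterol": "cholesterol_mg",
    "saturated_fat": "satfat_g",
    "sodium": "sodium_mg",
}


@dataclass(frozen=True)
class DailyValueTable:
    """Daily-value constants for the 11 tracked nutrients.

    All values must be strictly positive and the key set must be exactly
    :data:`NUTRIENTS`.
    """

    values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAILY_VALUES)
    )

    def __post_init__(self):
        keys = set(self.values)
        if keys != set(NUTRIENTS):
            raise UnknownNutrientError(
                f"daily-value table must cover exactly {sorted(NUTRIENTS)}, "
                f"got {sorted(keys)}"
            )
        for k, v in self.values.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"daily value for {k!r} must be finite and > 0")

    def __getitem__(self, nutrient: str) -> float:
        try:
            return self.values[nutrient]
        except KeyError:
            raise UnknownNutrientError(nutrient) from None


@dataclass
class NutrientProfile:
    """Per-item nutrient amounts in the canonical units.

    Absent keys are treated as missing; present amounts must be finite
    and non-negative.
    """

    amounts: dict[str, float]

    def __post_init__(self):
        for k, v in self.amounts.items():
            if k not in DEFAULT_DAILY_VALUES:
                raise UnknownNutrientError(k)
            if not np.isfinite(v):
                raise ValueError(f"amount for {k!r} must be finite")
            if v < 0:
                raise NegativeAmountError(f"amount for {k!r} is negative: {v}")

    def get(self, nutrient: str, missing: str = "error") -> float:
        if nutrient in self.amounts:
            return self.amounts[nutrient]
        if missing == "zero":
            return 0.0
        raise MissingNutrientError(nutrient)

    def is_missing(self, nutrient: str) -> bool:
        return nutrient not in self.amounts

    def scaled(self, c: float) -> "NutrientProfile":
        """Return a copy with every amount multiplied by ``c`` (c > 0)."""
        if c <= 0:
            raise ValueError("scale factor must be > 0")
        return NutrientProfile({k: v * c for k, v in self.amounts.items()})


@dataclass(frozen=True)
class NutrientDensityScore:
    value: float
    variant: str  # "rrr" | "rrr_macro"

    def __post_init__(self):
        if self.variant not in ("rrr", "rrr_macro"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"score must be finite and >= 0, got {self.value}")


def percent_dv(
    amount: float, nutrient: str, dv: DailyValueTable | None = None
) -> float:
    """Percent of the daily value: ``100 * amount / DV(nutrient)``."""
    dv = dv or DailyValueTable()
    if nutrient not in NUTRIENTS:
        raise UnknownNutrientError(nutrient)
    if amount < 0:
        raise NegativeAmountError(f"amount for {nutrient!r} is negative: {amount}")
    return 100.0 * amount / dv[nutrient]


def _score(
    profile: NutrientProfile,
    numerator_keys: Iterable[str],
    variant: str,
    dv: DailyValueTable | None,
    missing: str,
    max_score: float | None,
) -> NutrientDensityScore:
    dv = dv or DailyValueTable()
    num = [percent_dv(profile.get(k, missing), k, dv) for k in numerator_keys]
    den = [percent_dv(profile.get(k, missing), k, dv) for k in RESTRICTED]
    mean_den = float(np.mean(den))
    if mean_den == 0.0:
        raise UndefinedDenominatorError(
            "mean restricted %DV is zero; the ratio is undefined"
        )
    value = float(np.mean(num)) / mean_den
    if max_score is not None:
        value = min(value, max_score)
    return NutrientDensityScore(value=value, variant=variant)


def compute_rrr(
    profile: NutrientProfile,
    dv: DailyValueTable | None = None,
    missing: str = "error",
    max_score: float | None = None,
) -> NutrientDensityScore:
    """Mean %DV of the six recommended nutrients over the five restricted."""
    return _score(profile, RECOMMENDED, "rrr", dv, missing, max_score)


def compute_rrr_macro(
    profile: NutrientProfile,
    dv: DailyValueTable | None = None,
    missing: str = "error",
    max_score: float | None = None,
) -> NutrientDensityScore:
    """Macro variant: only protein and fiber in the numerator."""
    return _score(profile, MACRO_RECOMMENDED, "rrr_macro", dv, missing, max_score)


def score_frame(
    frame: pd.DataFrame,
    variant: str = "rrr_macro",
    missing: str = "error",
    dv: DailyValueTable | None = None,
) -> pd.Series:
    """Vectorized scoring of a table using the canonical CSV columns.

    Rows are scored independently; the returned series shares the frame's
    index.  ``missing='zero'`` treats absent columns / NaN cells as zero.
    """
    if variant not in ("rrr", "rrr_macro"):
        raise ValueError(f"unknown variant {variant!r}")
    dv = dv or DailyValueTable()
    num_keys = RECOMMENDED if variant == "rrr" else MACRO_RECOMMENDED

    def pct(keys):
        cols = []
        for k in keys:
            col = CSV_COLUMNS[k]
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                if missing == "zero":
                    vals = vals.fillna(0.0)
                elif vals.isna().any():
                    raise MissingNutrientError(
                        f"column {col!r} has missing values and missing='error'"
                    )
            elif missing == "zero":
                vals = pd.Series(0.0, index=frame.index)
            else:
                raise MissingNutrientError(f"column {col!r} absent")
            if (vals < 0).any():
                raise NegativeAmountError(f"column {col!r} has negative values")
            cols.append(100.0 * vals / dv[k])
        return pd.concat(cols, axis=1).mean(axis=1)

    den = pct(RESTRICTED)
    if (den == 0).any():
        raise UndefinedDenominatorError("some rows have zero mean restricted %DV")
    return pct(num_keys) / den


def profile_from_row(row: Mapping[str, float]) -> NutrientProfile:
    """Build a profile from a canonical-CSV row, skipping NaN cells."""
    amounts = {}
    for k, col in CSV_COLUMNS.items():
        if col in row and pd.notna(row[col]):
            amounts[k] = float(row[col])
    return NutrientProfile(amounts)
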