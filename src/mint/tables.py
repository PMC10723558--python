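"""Tabular I/O: food-item tables, menus, region maps, prediction files.

Readers collect malformed rows (with their source line numbers) instead
of silently dropping them; CSV writing uses standard quoting so names
containing commas or unicode round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .nutrients import CSV_COLUMNS

ITEM_COLUMNS = ["name"] + list(CSV_COLUMNS.values())
PREDICTION_COLUMNS = ["name", "predicted_category", "score", "ci_low", "ci_high"]


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


def _validate_items(frame: pd.DataFrame, line_offset: int) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    bad_idx = []
    for pos, (idx, row) in enumerate(frame.iterrows()):
        line = pos + line_offset
        name = row.get("name")
        if not isinstance(name, str) or not name.strip():
            errors.append(RowError(line, "missing or empty name"))
            bad_idx.append(idx)
            continue
        for col in CSV_COLUMNS.values():
            if col in frame.columns and pd.notna(row[col]):
                try:
                    val = float(row[col])
                except (TypeError, ValueError):
                    errors.append(RowError(line, f"non-numeric {col}: {row[col]!r}"))
                    bad_idx.append(idx)
                    break
                if val < 0:
                    errors.append(RowError(line, f"negative {col}: {val}"))
                    bad_idx.append(idx)
                    break
    good = frame.drop(index=bad_idx).reset_index(drop=True)
    return good, errors


def read_items(path: str | Path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read a food-item table (CSV or JSON records).

    Returns the valid rows and a list of row errors with line numbers
    (CSV data starts at line 2; JSON rows are numbered from 1).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
        frame = pd.DataFrame.from_records(records)
        offset = 1
    else:
        frame = pd.read_csv(path, encoding="utf-8")
        offset = 2  # header is line 1
    return _validate_items(frame, offset)


def write_items(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, encoding="utf-8")


def write_predictions(results, path: str | Path) -> None:
    """Write prediction rows (``PredictionResult`` objects or a frame)."""
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = pd.DataFrame(
            [
                {
                    "name": r.name,
                    "predicted_category": r.predicted_category,
                    "score": r.point_estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
                for r in results
            ]
        )
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.10g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def read_menus(path: str | Path) -> pd.DataFrame:
    """Menu table: ``restaurant_id, item_name[, rrr_macro]``."""
    frame = pd.read_csv(path, encoding="utf-8")
    missing = {"restaurant_id", "item_name"} - set(frame.columns)
    if missing:
        raise ValueError(f"menu table missing columns: {sorted(missing)}")
    return frame


def read_region_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, encoding="utf-8", dtype=str)
    missing = {"restaurant_id", "region"} - set(frame.columns)
    if missing:
        raise ValueError(f"region map missing columns: {sorted(missing)}")
    return dict(zip(frame["restaurant_id"], frame["region"]))
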