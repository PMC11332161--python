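"""Reading and writing the trial-table and item-metadata CSV schemas.

Canonical trial schema (header, comma-separated)::

    subject_id,item_id,veracity,favorability,response,confidence,presentation_index

with veracity in {true_news, false_news}, favorability in {pro_democrat,
pro_republican, unclassified}, response the literal string "true"/"false"
and confidence an integer 1..4.  External exports with different column
names (e.g. a repository deposit) are mapped through a rename dictionary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .sdt import FAVORABILITIES, RESPONSES, TRIAL_COLUMNS, VERACITIES


class SchemaError(ValueError):
    """A trial table violated the canonical schema; rows are 1-based data rows."""


def read_trials(path: str | Path, rename: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial table; malformed rows are reported by number."""
    df = pd.read_csv(path, dtype={"subject_id": str, "item_id": str, "response": str})
    if rename:
        df = df.rename(columns=dict(rename))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[TRIAL_COLUMNS]
    problems: list[str] = []

    def check(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = (df.index[mask] + 1).tolist()[:10]
            problems.append(f"{what} at rows {rows}")

    check(~df["veracity"].isin(VERACITIES), "invalid veracity")
    check(~df["favorability"].isin(FAVORABILITIES), "invalid favorability")
    check(~df["response"].astype(str).isin(RESPONSES), "invalid response")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    check(~conf.isin([1, 2, 3, 4]), "invalid confidence")
    idx = pd.to_numeric(df["presentation_index"], errors="coerce")
    check(idx.isna() | (idx < 0) | (idx != idx.astype("Int64")), "invalid presentation_index")
    dup = df.duplicated(subset=["subject_id", "item_id"], keep=False)
    check(dup, "duplicate (subject_id, item_id)")
    if problems:
        raise SchemaError("; ".join(problems))
    df["confidence"] = conf.astype(int)
    df["presentation_index"] = idx.astype(int)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_items(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"item_id": str})
    needed = ["item_id", "veracity", "favorability"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"item table missing columns: {missing}")
    if "in_equated" not in df.columns:
        df["in_equated"] = False
    return df


def write_items(items: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    items.to_csv(path, index=False)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x: object) -> object:
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
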