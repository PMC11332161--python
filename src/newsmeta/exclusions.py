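"""Subject-exclusion cascade applied before the statistical battery.

Stages, in order: (1) self-reported lack of effort; (2) incomplete runs;
(3) the quartile-based outlier labeling rule applied jointly to d' and
m-ratio (flagged if outside the [Q1 - g*IQR, Q3 + g*IQR] bounds on either
measure, bounds computed once on the sample passing stages 1-2); (4)
negative m-ratio.  A subject excluded at one stage is not re-evaluated
later, and each exclusion carries exactly one primary reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_G = 2.2

SUMMARY_COLUMNS = [
    "subject_id",
    "completed_all",
    "effort_flag",
    "d_prime",
    "m_ratio",
]


def outlier_labeling_bounds(values: Sequence[float], g: float = DEFAULT_G) -> tuple[float, float]:
    """Outlier-labeling bounds (Q1 - g*IQR, Q3 + g*IQR).

    Quartiles use linear interpolation between order statistics (numpy's
    default quantile convention); requires at least 4 values.  The default
    multiplier g = 2.2 follows the outlier-labeling literature.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("outlier labeling needs at least 4 values")
    if g <= 0:
        raise ValueError("g must be positive")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    return float(q1 - g * iqr), float(q3 + g * iqr)


@dataclass
class ExclusionLog:
    """Per-stage exclusion bookkeeping."""

    stages: list[dict]
    n_input: int
    n_retained: int
    bounds: dict[str, tuple[float, float]]

    def counts(self) -> dict[str, int]:
        return {s["reason"]: s["count"] for s in self.stages}

    def to_json_obj(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "stages": self.stages,
        }


def apply_exclusions(
    summaries: pd.DataFrame,
    g: float = DEFAULT_G,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the four-stage cascade; returns (retained table, log).

    ``summaries`` must carry :data:`SUMMARY_COLUMNS`.  Passing precomputed
    ``bounds`` (e.g. from a previous run) disables bounds re-estimation,
    which makes the cascade idempotent on its own output.  An empty retained
    set is legal and reported in the log.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"summaries missing columns: {missing}")
    df = summaries.reset_index(drop=True)
    alive = np.ones(len(df), dtype=bool)
    stages: list[dict] = []

    def drop(mask: np.ndarray, stage: int, reason: str) -> None:
        ids = df.loc[mask, "subject_id"].astype(str).tolist()
        stages.append({"stage": stage, "reason": reason, "subject_ids": ids, "count": len(ids)})
        alive[mask] = False

    drop(alive & df["effort_flag"].astype(bool).to_numpy(), 1, "lack_of_effort")
    drop(alive & ~df["completed_all"].astype(bool).to_numpy(), 2, "incomplete")

    completing = df[alive]
    if completing[["d_prime", "m_ratio"]].isna().any().any():
        raise ValueError("d_prime and m_ratio must be present for all completing subjects")
    if bounds is None:
        if len(completing) >= 4:
            bounds = {
                "d_prime": outlier_labeling_bounds(completing["d_prime"], g),
                "m_ratio": outlier_labeling_bounds(completing["m_ratio"], g),
            }
        else:  # too few completing subjects to estimate quartiles
            bounds = {"d_prime": (-np.inf, np.inf), "m_ratio": (-np.inf, np.inf)}
    d_lo, d_hi = bounds["d_prime"]
    m_lo, m_hi = bounds["m_ratio"]
    dp = df["d_prime"].to_numpy(dtype=float)
    mr = df["m_ratio"].to_numpy(dtype=float)
    outlier = (dp < d_lo) | (dp > d_hi) | (mr < m_lo) | (mr > m_hi)
    drop(alive & outlier, 3, "outlier_labeling")
    drop(alive & (mr < 0), 4, "negative_m_ratio")

    retained = df[alive].reset_index(drop=True)
    log = ExclusionLog(
        stages=stages, n_input=len(df), n_retained=len(retained), bounds=bounds
    )
    return retained, log
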