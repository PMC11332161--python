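"""Type-1/type-2 signal-detection classification of true/false news judgments.

The type-1 judgment is the binary true/false call on a headline; the type-2
judgment is whether the 4-point confidence rating discriminates the subject's
own correct from incorrect type-1 calls.  "True" headlines are the signal
class: a *hit* is a true item called true, a *false alarm* is a false item
called true.  With that convention a positive criterion ``c`` means a strict
threshold for calling an item true (a "false bias").

Trial tables are plain pandas DataFrames with the columns in
:data:`TRIAL_COLUMNS`; veracity is ``{"true_news", "false_news"}``,
favorability is ``{"pro_democrat", "pro_republican", "unclassified"}``, the
response is the literal string ``"true"`` or ``"false"`` and confidence is an
integer 1..4 (1 = not confident, 4 = very confident).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

TRIAL_COLUMNS = [
    "subject_id",
    "item_id",
    "veracity",
    "favorability",
    "response",
    "confidence",
    "presentation_index",
]

TRUE_NEWS = "true_news"
FALSE_NEWS = "false_news"
VERACITIES = (TRUE_NEWS, FALSE_NEWS)
FAVORABILITIES = ("pro_democrat", "pro_republican", "unclassified")
RESPONSES = ("true", "false")

#: confidence ratings counted as "high"
HIGH_CONFIDENCE = (3, 4)

CorrectionPolicy = Literal["half_count", "loglinear", "none"]


@dataclass(frozen=True)
class TrialRecord:
    """One headline judgment by one subject."""

    subject_id: str
    item_id: str
    veracity: str
    favorability: str
    response: str
    confidence: int
    presentation_index: int


@dataclass(frozen=True)
class Type1Counts:
    """The four type-1 cells for a single subject."""

    hits: int
    misses: int
    correct_rejections: int
    false_alarms: int

    @property
    def n_true(self) -> int:
        return self.hits + self.misses

    @property
    def n_false(self) -> int:
        return self.correct_rejections + self.false_alarms

    @property
    def n_trials(self) -> int:
        return self.n_true + self.n_false


@dataclass(frozen=True)
class Type2Counts:
    """The eight (stimulus x response x confidence) cells for one subject.

    ``counts[s, r, h]`` with stimulus ``s`` (0 = false_news, 1 = true_news),
    response ``r`` (0 = "false", 1 = "true") and binarized confidence ``h``
    (0 = low, 1 = high).  Correctness is implied: a cell is correct iff
    ``s == r``.
    """

    counts: np.ndarray  # shape (2, 2, 2), int

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (2, 2, 2):
            raise ValueError("Type2Counts requires a (2, 2, 2) array")
        object.__setattr__(self, "counts", arr)

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    def type1(self) -> Type1Counts:
        """Collapse over confidence back to the type-1 cells."""
        c = self.counts.sum(axis=2)
        return Type1Counts(
            hits=int(c[1, 1]),
            misses=int(c[1, 0]),
            correct_rejections=int(c[0, 0]),
            false_alarms=int(c[0, 1]),
        )

    def by_response_correct(self) -> dict[tuple[str, bool, str], int]:
        """Counts keyed by (response, correct, confidence level)."""
        out: dict[tuple[str, bool, str], int] = {}
        for s in (0, 1):
            for r in (0, 1):
                for h in (0, 1):
                    key = (RESPONSES[1 - r], s == r, "high" if h else "low")
                    out[key] = out.get(key, 0) + int(self.counts[s, r, h])
        return out


@dataclass(frozen=True)
class SDTEstimates:
    """Point estimates of discernment and response bias for one subject."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    c: float
    c_prime: float | None
    correction_applied: str  # "none" or "adjusted"


def binarize_confidence(rating: int) -> str:
    """Map a 1..4 confidence rating to ``"low"`` (1, 2) or ``"high"`` (3, 4)."""
    if rating not in (1, 2, 3, 4):
        raise ValueError(f"invalid confidence: {rating!r} (must be 1..4)")
    return "high" if rating in HIGH_CONFIDENCE else "low"


def _as_frame(trials: pd.DataFrame | Sequence[TrialRecord]) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame([t.__dict__ for t in trials])


def classify_trials(
    trials: pd.DataFrame | Sequence[TrialRecord],
) -> tuple[Type1Counts, Type2Counts]:
    """Classify one subject's trials into the type-1 and type-2 cells.

    Every trial lands in exactly one type-1 cell (hit / miss / correct
    rejection / false alarm) and one type-2 cell (the same crossed with
    binarized confidence).  The caller is responsible for grouping: all rows
    must belong to a single subject.
    """
    df = _as_frame(trials)
    if len(df) == 0:
        raise ValueError("no trials")
    if df["subject_id"].nunique() > 1:
        raise ValueError("classify_trials expects trials from a single subject")
    conf = df["confidence"].to_numpy()
    if not np.isin(conf, [1, 2, 3, 4]).all():
        bad = sorted(set(conf) - {1, 2, 3, 4})
        raise ValueError(f"invalid confidence: {bad}")
    ver = df["veracity"].to_numpy()
    if not np.isin(ver, VERACITIES).all():
        raise ValueError("veracity must be 'true_news' or 'false_news'")
    resp = df["response"].astype(str).to_numpy()
    if not np.isin(resp, RESPONSES).all():
        raise ValueError("response must be 'true' or 'false'")

    s = (ver == TRUE_NEWS).astype(int)
    r = (resp == "true").astype(int)
    h = np.isin(conf, HIGH_CONFIDENCE).astype(int)
    counts = np.zeros((2, 2, 2), dtype=int)
    np.add.at(counts, (s, r, h), 1)
    t2 = Type2Counts(counts)
    return t2.type1(), t2


def correct_rates(
    counts: Type1Counts, policy: CorrectionPolicy = "half_count"
) -> tuple[float, float, bool]:
    """Hit/false-alarm rates with an extreme-rate correction.

    ``half_count`` replaces a rate of 0 with 1/(2N) and a rate of 1 with
    1 - 1/(2N), per-veracity, only when the rate is extreme.  ``loglinear``
    adds 0.5 to every cell unconditionally.  ``none`` leaves rates untouched
    (z-scores of 0/1 are infinite).  Returns (hit_rate, fa_rate, adjusted).
    """
    n_true, n_false = counts.n_true, counts.n_false
    if n_true == 0 or n_false == 0:
        raise ValueError("undefined rate: need at least one trial of each veracity")
    hr = counts.hits / n_true
    fr = counts.false_alarms / n_false
    adjusted = False
    if policy == "loglinear":
        hr2 = (counts.hits + 0.5) / (n_true + 1)
        fr2 = (counts.false_alarms + 0.5) / (n_false + 1)
        adjusted = (hr2 != hr) or (fr2 != fr)
        hr, fr = hr2, fr2
    elif policy == "half_count":
        if hr == 0.0:
            hr, adjusted = 1.0 / (2 * n_true), True
        elif hr == 1.0:
            hr, adjusted = 1.0 - 1.0 / (2 * n_true), True
        if fr == 0.0:
            fr, adjusted = 1.0 / (2 * n_false), True
        elif fr == 1.0:
            fr, adjusted = 1.0 - 1.0 / (2 * n_false), True
    elif policy != "none":
        raise ValueError(f"unknown correction policy: {policy!r}")
    return hr, fr, adjusted


def compute_type1_estimates(
    counts: Type1Counts, correction_policy: CorrectionPolicy = "half_count"
) -> SDTEstimates:
    """d', c and c' from type-1 counts.

    d' = z(HR) - z(FAR); c = -(z(HR) + z(FAR)) / 2; c' = c / d'.  c' is
    reported as None when |d'| < 1e-6 rather than +/-infinity.
    """
    hr, fr, adjusted = correct_rates(counts, correction_policy)
    zh, zf = ndtri(hr), ndtri(fr)
    d_prime = zh - zf
    c = -0.5 * (zh + zf)
    defined = np.isfinite(d_prime) and abs(d_prime) >= 1e-6 and np.isfinite(c)
    c_prime = c / d_prime if defined else None
    return SDTEstimates(
        hit_rate=hr,
        fa_rate=fr,
        d_prime=float(d_prime),
        c=float(c),
        c_prime=None if c_prime is None else float(c_prime),
        correction_applied="adjusted" if adjusted else "none",
    )


def subset_trials(
    trials: pd.DataFrame,
    by: str,
    items: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select a trial subset used by the robustness analyses.

    ``by`` is one of:

    - ``"pro_democrat"`` / ``"pro_republican"``: items favorable to that side;
    - ``"equated_set"``: the politically equated item subset (requires an
      ``items`` table with an ``in_equated`` column, keyed by item_id);
    - ``"even_index"`` / ``"odd_index"``: split-half by presentation-order
      parity (items were shown in randomized order, so presentation parity is
      the conventional even/odd split).
    """
    df = _as_frame(trials)
    if by in ("pro_democrat", "pro_republican"):
        out = df[df["favorability"] == by]
    elif by == "equated_set":
        if items is None or "in_equated" not in items.columns:
            raise ValueError("equated_set subset requires an items table with 'in_equated'")
        keep = set(items.loc[items["in_equated"].astype(bool), "item_id"])
        out = df[df["item_id"].isin(keep)]
    elif by == "even_index":
        out = df[df["presentation_index"] % 2 == 0]
    elif by == "odd_index":
        out = df[df["presentation_index"] % 2 == 1]
    else:
        raise ValueError(f"unknown subset: {by!r}")
    if len(out) == 0:
        raise ValueError(f"subset {by!r} is empty")
    return out.reset_index(drop=True)


def type1_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject d'/c/c' point estimates for a multi-subject trial table."""
    rows = []
    for sid, grp in trials.groupby("subject_id", sort=True):
        t1, _ = classify_trials(grp)
        est = compute_type1_estimates(t1)
        rows.append(
            {
                "subject_id": sid,
                "n_trials": t1.n_trials,
                "hit_rate": est.hit_rate,
                "fa_rate": est.fa_rate,
                "d_prime": est.d_prime,
                "c": est.c,
                "c_prime": est.c_prime,
                "correction_applied": est.correction_applied,
            }
        )
    return pd.DataFrame(rows)


def type2_count_table(trials: pd.DataFrame) -> dict[str, Type2Counts]:
    """Type2Counts per subject, keyed by subject_id."""
    return {
        str(sid): classify_trials(grp)[1]
        for sid, grp in trials.groupby("subject_id", sort=True)
    }
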