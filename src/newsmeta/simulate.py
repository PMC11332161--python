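"""Generative observer and cohort simulator emulating the study design.

The task: each synthetic subject judges a set of news headlines (70 true and
70 false in the full set) as true or false and rates confidence 1-4.  The
generative observer is an equal-variance Gaussian SDT observer with a
post-decisional confidence stage:

- decision evidence  x  ~ Normal(+d'/2 for true items, -d'/2 for false, 1);
  the subject answers "true" iff x > c;
- confidence evidence x2 = x + Normal(0, meta_noise_sigma): the same
  evidence corrupted by independent Gaussian noise at the confidence stage;
- confidence 1..4 by comparing x2 to two ordered thresholds offset from c on
  the response's side (offsets tau_conf), so that binarizing at 3-vs-2
  recovers the low/high split at the first offset.

With meta_noise_sigma = 0 confidence uses exactly the decision evidence and
the observer is metacognitively ideal (m-ratio 1); increasing sigma drives
the m-ratio below 1, which is the single knob the cohort-level calibration
turns (the study-like default targets a sample mean m-ratio of 0.86).

Demographic structure mirrors the study: 2 parties x 2 partisanship
strengths x 4 age bins (16 cells), education 1..6 and gender recorded per
subject, with additive group effects on the generative parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .sdt import FALSE_NEWS, TRIAL_COLUMNS, TRUE_NEWS

PARTIES = ("democrat", "republican")
STRENGTHS = ("strong", "weak")
AGE_BINS = ("18-32", "33-47", "48-62", "63+")
#: midpoints used when a continuous age is needed for correlations
AGE_BIN_RANGES = {"18-32": (18, 32), "33-47": (33, 47), "48-62": (48, 62), "63+": (63, 84)}
GENDERS = ("man", "woman")

#: meta-noise sigma whose large-sample m-ratio is ~0.86 at the default
#: observer (the study-like regime); see calibrate_meta_noise.
DEFAULT_META_NOISE = 0.33


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth generative parameters for one synthetic subject."""

    d_prime_true: float = 1.8
    c_true: float = 0.1
    meta_noise_sigma: float = DEFAULT_META_NOISE
    tau_conf: tuple[float, float] = (0.5, 1.5)
    demographics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.meta_noise_sigma < 0:
            raise ValueError("meta_noise_sigma must be >= 0")
        t1, t2 = self.tau_conf
        if not (0 < t1 < t2):
            raise ValueError("tau_conf thresholds must be strictly ordered and positive")


@dataclass(frozen=True)
class StimulusSet:
    """An item list with veracity and political-favorability tags."""

    name: str
    items: pd.DataFrame  # item_id, veracity, favorability, in_equated

    @property
    def n_items(self) -> int:
        return len(self.items)


def generate_stimulus_set(name: str) -> StimulusSet:
    """The study's stimulus compositions.

    ``full_140``: 70 true + 70 false items; the false items split 54
    pro-Republican / 16 pro-Democrat and the true items 39 pro-Democrat /
    31 pro-Republican.  ``equated_64``: the politically equated subset with
    16 items in each veracity x favorability cell (every pro-Democrat false
    item, and a fixed 16 of each other cell).  Item ids are deterministic.
    """
    if name not in ("full_140", "equated_64"):
        raise ValueError(f"unknown stimulus set: {name!r}")
    rows = []

    def add(prefix: str, n: int, veracity: str, favorability: str, n_equated: int) -> None:
        start = len([r for r in rows if r["veracity"] == veracity])
        for i in range(n):
            rows.append(
                {
                    "item_id": f"{prefix}{start + i + 1:03d}",
                    "veracity": veracity,
                    "favorability": favorability,
                    "in_equated": i < n_equated,
                }
            )

    add("T", 39, TRUE_NEWS, "pro_democrat", 16)
    add("T", 31, TRUE_NEWS, "pro_republican", 16)
    add("F", 16, FALSE_NEWS, "pro_democrat", 16)
    add("F", 54, FALSE_NEWS, "pro_republican", 16)
    items = pd.DataFrame(rows)
    if name == "equated_64":
        items = items[items["in_equated"]].reset_index(drop=True)
    return StimulusSet(name=name, items=items)


def _confidence_from_evidence(
    x2: np.ndarray, responded_true: np.ndarray, c: np.ndarray, tau: tuple[float, float]
) -> np.ndarray:
    """Map confidence evidence to the 1..4 scale, per response side."""
    t1, t2 = tau
    up = 1 + (x2 > c).astype(int) + (x2 > c + t1).astype(int) + (x2 > c + t2).astype(int)
    down = 1 + (x2 < c).astype(int) + (x2 < c - t1).astype(int) + (x2 < c - t2).astype(int)
    return np.where(responded_true, up, down)


def simulate_trials(
    observer: ObserverParams,
    items: pd.DataFrame,
    rng: np.random.Generator,
    subject_id: str = "sim",
    c_item_shift: np.ndarray | None = None,
    d_item_shift: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one subject's full run over ``items`` in randomized order.

    Optional per-item shifts let cohort-level congruence effects move the
    criterion or sensitivity for particular item classes.
    """
    n = len(items)
    if n == 0:
        raise ValueError("no items")
    is_true = (items["veracity"] == TRUE_NEWS).to_numpy()
    d = observer.d_prime_true + (d_item_shift if d_item_shift is not None else 0.0)
    c = observer.c_true + (c_item_shift if c_item_shift is not None else 0.0)
    c = np.broadcast_to(np.asarray(c, float), (n,))
    mu = np.where(is_true, d / 2.0, -d / 2.0)
    x = rng.normal(mu, 1.0)
    responded_true = x > c
    x2 = x + rng.normal(0.0, observer.meta_noise_sigma, size=n)
    conf = _confidence_from_evidence(x2, responded_true, c, observer.tau_conf)
    order = rng.permutation(n)
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "item_id": items["item_id"].to_numpy(),
            "veracity": items["veracity"].to_numpy(),
            "favorability": items["favorability"].to_numpy(),
            "response": np.where(responded_true, "true", "false"),
            "confidence": conf,
            "presentation_index": np.empty(n, dtype=int),
        }
    )
    df.loc[order, "presentation_index"] = np.arange(n)
    return df.sort_values("presentation_index").reset_index(drop=True)[TRIAL_COLUMNS]


def simulate_trial(
    observer: ObserverParams, item: Mapping[str, object], rng: np.random.Generator
) -> pd.Series:
    """Single-trial convenience wrapper around :func:`simulate_trials`."""
    items = pd.DataFrame([dict(item)])
    return simulate_trials(observer, items, rng).iloc[0]


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Effect:
    """An additive shift on a generative parameter for matching subjects.

    ``param`` is one of ``d_prime``, ``c``, ``meta_noise``.  ``where``
    matches subject demographics (e.g. ``{"party": "democrat", "strength":
    "strong"}``); ``item_where`` (criterion/sensitivity effects only)
    additionally restricts the shift to matching items, e.g. a "true bias"
    for politically congruent headlines.
    """

    param: str
    shift: float
    where: Mapping[str, object] = field(default_factory=dict)
    item_where: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.param not in ("d_prime", "c", "meta_noise"):
            raise ValueError(f"unknown effect parameter: {self.param!r}")
        if self.item_where and self.param == "meta_noise":
            raise ValueError("item-level effects apply to d_prime or c only")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort.

    By default the 16 demographic cells (party x strength x age bin) each
    receive ``n_per_cell`` subjects; ``cell_sizes`` overrides the party x
    strength margins with study-like unequal counts, distributed as evenly
    as possible over age bins.  Between-subject spread around the cell means
    uses ``subject_sd`` (d'), ``subject_sd_c`` and ``subject_sd_noise``.
    """

    n_per_cell: int = 8
    cell_sizes: Mapping[tuple[str, str], int] | None = None
    stimulus_set: str = "full_140"
    baseline: ObserverParams = field(default_factory=ObserverParams)
    effects: tuple[Effect, ...] = ()
    subject_sd: float = 0.55
    subject_sd_c: float = 0.2
    subject_sd_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_sizes is None and self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")


def _matches(demo: Mapping[str, object], where: Mapping[str, object]) -> bool:
    return all(demo.get(k) == v for k, v in where.items())


def _subject_frame(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    if config.cell_sizes is not None:
        for (party, strength), total in config.cell_sizes.items():
            base, extra = divmod(total, len(AGE_BINS))
            for j, age_bin in enumerate(AGE_BINS):
                rows += [(party, strength, age_bin)] * (base + (1 if j < extra else 0))
    else:
        for party in PARTIES:
            for strength in STRENGTHS:
                for age_bin in AGE_BINS:
                    rows += [(party, strength, age_bin)] * config.n_per_cell
    df = pd.DataFrame(rows, columns=["party", "strength", "age_bin"])
    n = len(df)
    df.insert(0, "subject_id", [f"s{i:04d}" for i in range(n)])
    lo = np.array([AGE_BIN_RANGES[b][0] for b in df["age_bin"]])
    hi = np.array([AGE_BIN_RANGES[b][1] for b in df["age_bin"]])
    df["age"] = rng.integers(lo, hi + 1)
    df["education"] = rng.integers(1, 7, size=n)
    df["gender"] = np.where(np.arange(n) % 2 == 0, "man", "woman")
    return df


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth table).

    Fully reproducible from ``config.seed``: identical configs give
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    stim = generate_stimulus_set(config.stimulus_set)
    subjects = _subject_frame(config, rng)
    base = config.baseline

    item_effects = [e for e in config.effects if e.item_where]
    subj_effects = [e for e in config.effects if not e.item_where]

    truth_rows = []
    trial_frames = []
    items = stim.items
    for row in subjects.itertuples(index=False):
        demo = {
            "party": row.party,
            "strength": row.strength,
            "age_bin": row.age_bin,
            "age": int(row.age),
            "education": int(row.education),
            "gender": row.gender,
        }
        d_mean, c_mean, s_mean = base.d_prime_true, base.c_true, base.meta_noise_sigma
        for e in subj_effects:
            if _matches(demo, e.where):
                if e.param == "d_prime":
                    d_mean += e.shift
                elif e.param == "c":
                    c_mean += e.shift
                else:
                    s_mean += e.shift
        d_i = d_mean + config.subject_sd * rng.standard_normal()
        c_i = c_mean + config.subject_sd_c * rng.standard_normal()
        s_i = s_mean + config.subject_sd_noise * rng.standard_normal()
        if s_mean < 0:
            raise ValueError(f"effect specification yields negative meta noise ({s_mean:.3f})")
        d_i, s_i = max(d_i, 0.05), max(s_i, 0.0)
        obs = ObserverParams(d_i, c_i, s_i, base.tau_conf, demo)

        c_shift = np.zeros(len(items))
        d_shift = np.zeros(len(items))
        for e in item_effects:
            if _matches(demo, e.where):
                mask = np.ones(len(items), dtype=bool)
                for k, v in e.item_where.items():
                    mask &= (items[k] == v).to_numpy()
                if e.param == "c":
                    c_shift[mask] += e.shift
                else:
                    d_shift[mask] += e.shift
        trial_frames.append(
            simulate_trials(
                obs,
                items,
                rng,
                subject_id=row.subject_id,
                c_item_shift=c_shift if item_effects else None,
                d_item_shift=d_shift if item_effects else None,
            )
        )
        truth_rows.append(
            {
                "subject_id": row.subject_id,
                "d_prime_true": d_i,
                "c_true": c_i,
                "meta_noise_sigma": s_i,
                **demo,
            }
        )
    trials = pd.concat(trial_frames, ignore_index=True)
    return trials, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# population-level (analytic) metacognition of the generative observer
# ---------------------------------------------------------------------------


def population_cell_probabilities(observer: ObserverParams) -> np.ndarray:
    """Exact 8-cell probabilities of the generative observer (balanced items).

    Decision evidence x and confidence evidence x2 = x + noise are jointly
    Gaussian, so each (response, high-confidence) cell is a bivariate-normal
    orthant probability.  Indexed like Type2Counts: (stimulus, response,
    binarized confidence).
    """
    d, c, sig = observer.d_prime_true, observer.c_true, observer.meta_noise_sigma
    t1 = observer.tau_conf[0]  # binarization boundary offset
    sd2 = np.sqrt(1.0 + sig**2)
    rho = 1.0 / sd2
    out = np.empty((2, 2, 2))
    for s, mu in ((0, -d / 2.0), (1, d / 2.0)):
        p_r1 = ndtr((mu - c))
        if sig < 1e-5:  # the joint evidence degenerates to a single variable
            p_r1_high = ndtr(mu - (c + t1))
            p_r0_high = ndtr((c - t1) - mu)
        else:
            bvn = stats.multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            )
            a = (c - mu) / 1.0
            b = (c + t1 - mu) / sd2
            # P(u > a, v > b) for standardized (u, v) with correlation rho
            p_r1_high = 1.0 - ndtr(a) - ndtr(b) + bvn.cdf([a, b])
            b2 = (c - t1 - mu) / sd2
            p_r0_high = bvn.cdf([a, b2])
        out[s, 1, 1] = 0.5 * p_r1_high
        out[s, 1, 0] = 0.5 * (p_r1 - p_r1_high)
        out[s, 0, 1] = 0.5 * p_r0_high
        out[s, 0, 0] = 0.5 * ((1.0 - p_r1) - p_r0_high)
    return np.clip(out, 0.0, 1.0)


def effective_meta_d(observer: ObserverParams) -> float:
    """The meta-d' implied by the observer's population confidence behavior.

    Fits the meta-d' measurement model (type-1 parameters fixed at the
    generative truth) to the exact population cell probabilities by minimum
    Kullback-Leibler divergence.  With zero meta noise this returns d'
    exactly; it decreases monotonically as meta noise grows.  This is the
    ground truth against which fitted meta-d' values are judged and the
    quantity the noise calibration inverts.
    """
    from .metad import _cell_probs  # local import to avoid a cycle at import time

    d, c = observer.d_prime_true, observer.c_true
    if observer.meta_noise_sigma == 0.0:
        return float(d)
    pop = population_cell_probabilities(observer)

    def neg_xent(v: np.ndarray) -> float:
        md, lt, lf = v
        model = _cell_probs(
            np.float64(d), np.float64(c), np.float64(md),
            np.exp(np.float64(lt)), np.exp(np.float64(lf)),
        )
        return -float(np.sum(pop * np.log(np.clip(model, 1e-300, None))))

    t1 = observer.tau_conf[0]
    x0 = np.array([d / np.sqrt(1 + observer.meta_noise_sigma**2), np.log(t1), np.log(t1)])
    res = optimize.minimize(neg_xent, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 3000})
    return float(res.x[0])


def effective_m_ratio(observer: ObserverParams) -> float:
    """Population m-ratio of the generative observer."""
    return effective_meta_d(observer) / observer.d_prime_true


def calibrate_meta_noise(
    target_m_ratio: float, base_observer: ObserverParams | None = None
) -> float:
    """Meta-noise sigma whose population m-ratio equals ``target_m_ratio``.

    Inverts the (monotone decreasing) map sigma -> m-ratio by bisection on
    the analytic population model; valid targets lie in (0, 1].
    """
    if not (0.0 < target_m_ratio <= 1.0):
        raise ValueError("target m-ratio must be in (0, 1]")
    base = base_observer or ObserverParams()
    if target_m_ratio == 1.0:
        return 0.0

    def gap(sig: float) -> float:
        obs = ObserverParams(base.d_prime_true, base.c_true, sig, base.tau_conf)
        return effective_m_ratio(obs) - target_m_ratio

    lo = 1e-4
    if gap(lo) < 0:
        return lo
    hi = 1.0
    while gap(hi) > 0:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError(f"target m-ratio {target_m_ratio} unreachable")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-4))
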