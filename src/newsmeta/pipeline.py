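"""End-to-end orchestration: simulate/read -> classify -> fit -> exclude -> analyze.

A run is driven by a :class:`RunConfig` (YAML-loadable).  Stages:

1. acquire trials (synthetic cohort or external CSV) plus item metadata;
2. per-subject type-1 point estimates (d', c, c');
3. Bayesian meta-d' fits (vectorized across subjects) -> m-ratio;
4. the exclusion cascade;
5. the statistical battery, routed by stimulus set: analyses that directly
   examine biases (response bias, political favorability) use only the
   politically equated item subset;
6. artifact emission (CSV tables, JSON logs, a run manifest with the config
   hash, seed, versions and an R-hat summary).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exclusions import DEFAULT_G, apply_exclusions
from .io import read_items, read_trials, write_items, write_json, write_trials
from .metad import MCMCConfig, MetaDPriors, fit_metad_cohort
from .sdt import subset_trials, type1_table, type2_count_table
from .simulate import CohortConfig, Effect, ObserverParams, generate_stimulus_set, simulate_cohort
from . import stats as nstats

log = logging.getLogger("newsmeta")

DEFAULT_ANALYSES = {
    "demographics": True,
    "response_bias": True,
    "favorability": True,
    "quartiles": True,
    "splithalf": False,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    out_dir: str = "newsmeta_run"
    seed: int = 0
    stimulus_set: str = "full_140"
    cohort: CohortConfig | None = None
    trials_path: str | None = None
    items_path: str | None = None
    subjects_path: str | None = None  # demographics for external trials
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    g: float = DEFAULT_G
    analyses: dict = field(default_factory=lambda: dict(DEFAULT_ANALYSES))

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.trials_path is None):
            raise ValueError("exactly one input source: cohort or trials_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and raw["cohort"] is not None:
            c = dict(raw["cohort"])
            if "baseline" in c:
                c["baseline"] = ObserverParams(**c["baseline"])
            if "effects" in c:
                c["effects"] = tuple(Effect(**e) for e in c["effects"])
            if "cell_sizes" in c and c["cell_sizes"] is not None:
                c["cell_sizes"] = {tuple(k.split("/")): v for k, v in c["cell_sizes"].items()}
            raw["cohort"] = CohortConfig(**c)
        if "mcmc" in raw and raw["mcmc"] is not None:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        cfg = cls(**raw)
        return cfg

    def canonical(self) -> str:
        def norm(o):
            if isinstance(o, dict):
                return {
                    "/".join(k) if isinstance(k, tuple) else str(k): norm(v)
                    for k, v in o.items()
                }
            if isinstance(o, (list, tuple)):
                return [norm(v) for v in o]
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        return json.dumps(norm(asdict(self)), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _anova_rows(analysis: str, results) -> list[dict]:
    return [
        {
            "analysis": analysis,
            "effect": r.effect,
            "statistic": r.F,
            "df1": r.df_num,
            "df2": r.df_den,
            "estimate": r.MSE,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": r.p,
            "effect_size": r.partial_eta_squared,
        }
        for r in results
    ]


def _ttest_row(analysis: str, effect: str, r, bf01: float | None = None) -> dict:
    return {
        "analysis": analysis,
        "effect": effect + ("" if bf01 is None else f" (BF01={bf01:.2f})"),
        "statistic": r.t,
        "df1": r.df,
        "df2": np.nan,
        "estimate": np.nan,
        "ci_low": r.ci95[0],
        "ci_high": r.ci95[1],
        "p": r.p,
        "effect_size": r.cohens_d,
    }


def _corr_row(analysis: str, effect: str, rho: float, p: float, n: int) -> dict:
    return {
        "analysis": analysis,
        "effect": effect,
        "statistic": rho,
        "df1": n - 2,
        "df2": np.nan,
        "estimate": rho,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": p,
        "effect_size": rho,
    }


def demographic_battery(subjects: pd.DataFrame, dv: str, label: str) -> list[dict]:
    """Partisanship 2x2, age one-way, correlations, gender t-test and the
    standardized multiple regression for one dependent variable."""
    rows: list[dict] = []
    s = subjects.dropna(subset=[dv])
    rows += _anova_rows(
        f"{label}: partisanship x strength",
        nstats.anova_2x2_between(
            s[dv], s["party"], s["strength"], names=("partisanship", "strength")
        ),
    )
    for party in ("democrat", "republican"):
        grp = s[s["party"] == party]
        strong = grp.loc[grp["strength"] == "strong", dv]
        weak = grp.loc[grp["strength"] == "weak", dv]
        if len(strong) >= 2 and len(weak) >= 2:
            rows.append(
                _ttest_row(f"{label}: strong vs weak ({party})", "strong - weak",
                           nstats.ttest(strong, weak))
            )
    from .simulate import AGE_BINS

    rows += _anova_rows(
        f"{label}: age group",
        [nstats.anova_oneway(s[dv], s["age_bin"], order=list(AGE_BINS), effect="age_bin")],
    )
    rho, p = nstats.spearman(s[dv], s["age"])
    rows.append(_corr_row(f"{label}: age (continuous)", "spearman rho", rho, p, len(s)))
    rho, p = nstats.spearman(s[dv], s["education"])
    rows.append(_corr_row(f"{label}: education", "spearman rho", rho, p, len(s)))
    men = s.loc[s["gender"] == "man", dv]
    women = s.loc[s["gender"] == "woman", dv]
    tt = nstats.ttest(men, women)
    bf01 = nstats.jzs_bf01_ttest(men, women) if tt.p > 0.05 else None
    rows.append(_ttest_row(f"{label}: gender", "men - women", tt, bf01))
    preds = pd.DataFrame(
        {
            "partisanship": (s["party"] == "democrat").astype(float),
            "education": s["education"].astype(float),
            "gender": (s["gender"] == "man").astype(float),
            "age": s["age"].astype(float),
        }
    )
    reg = nstats.regression_std(s[dv], preds)
    for name, r in reg.iterrows():
        rows.append(
            {
                "analysis": f"{label}: regression (R2={reg.attrs['R2']:.3f})",
                "effect": name,
                "statistic": r["beta"] / r["se"],
                "df1": len(s) - 5,
                "df2": np.nan,
                "estimate": r["beta"],
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": r["p"],
                "effect_size": r["beta"],
            }
        )
    return rows


def favorability_battery(subjects: pd.DataFrame, dv_stub: str, label: str) -> list[dict]:
    """2x2 between-within ANOVA: partisanship x item favorability."""
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"],
                    "party": subjects["party"],
                    "item_type": side,
                    "dv": subjects[f"{dv_stub}_{suffix}"],
                }
            )
            for side, suffix in (("pro_democrat", "dem"), ("pro_republican", "rep"))
        ],
        ignore_index=True,
    ).dropna(subset=["dv"])
    counts = long.groupby("subject_id").size()
    long = long[long["subject_id"].isin(counts.index[counts == 2])]
    return _anova_rows(label, nstats.mixed_anova_2x2(long, dv="dv"))


def _fit_mratio(
    trials: pd.DataFrame, mcmc: MCMCConfig, priors: MetaDPriors | None = None
) -> pd.DataFrame:
    """Type-1 estimates + Bayesian meta-d' fits for every subject in a table."""
    t1 = type1_table(trials)
    counts = type2_count_table(trials)
    ids = list(counts.keys())
    fits = fit_metad_cohort([counts[i] for i in ids], priors=priors, config=mcmc,
                            subject_ids=ids)
    fdf = pd.DataFrame([f.to_record() for f in fits])
    return t1.merge(fdf, on="subject_id")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }

    # --- stage 1: input ----------------------------------------------------
    if config.cohort is not None:
        cohort = replace(config.cohort, seed=config.seed,
                         stimulus_set=config.stimulus_set)
        trials, truth = simulate_cohort(cohort)
        items = generate_stimulus_set(config.stimulus_set).items
        demo = truth.drop(columns=["d_prime_true", "c_true", "meta_noise_sigma"])
        truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        trials = read_trials(config.trials_path)
        items = read_items(config.items_path) if config.items_path else None
        demo = pd.read_csv(config.subjects_path) if config.subjects_path else None
    write_trials(trials, out / "trials.csv")
    if items is not None:
        write_items(items, out / "items.csv")
    n_subjects = trials["subject_id"].nunique()
    manifest["stages"]["input"] = {"n_subjects": int(n_subjects), "n_trials": int(len(trials))}
    log.info("input: %d subjects, %d trials", n_subjects, len(trials))

    # --- stages 2-3: estimation -------------------------------------------
    mcmc = replace(config.mcmc, seed=config.seed + 1)
    est = _fit_mratio(trials, mcmc)
    n_nonconv = int((~est["converged"]).sum())
    manifest["stages"]["fit"] = {
        "n_fit": len(est),
        "rhat_max": float(est["rhat_max"].max()),
        "n_not_converged": n_nonconv,
    }
    if n_nonconv:
        # surfaced, never silently dropped: convergence does not exclude
        log.warning("%d subjects with R-hat >= 1.01", n_nonconv)

    # --- stage 4: exclusions ----------------------------------------------
    summaries = est.rename(columns={"m_ratio_hat": "m_ratio"})[
        ["subject_id", "d_prime", "m_ratio"]
    ].copy()
    per_item = trials.groupby("subject_id").size()
    n_items = len(items) if items is not None else int(per_item.max())
    summaries["completed_all"] = summaries["subject_id"].map(per_item).eq(n_items).to_numpy()
    if demo is not None and "effort_flag" in demo.columns:
        summaries = summaries.merge(demo[["subject_id", "effort_flag"]], on="subject_id")
    else:
        summaries["effort_flag"] = False
    retained, excl_log = apply_exclusions(summaries, g=config.g)
    write_json(excl_log.to_json_obj(), out / "exclusions.json")
    manifest["stages"]["exclusions"] = excl_log.counts() | {
        "n_retained": excl_log.n_retained
    }
    log.info("exclusions: %s", excl_log.counts())

    subjects = retained.merge(est.drop(columns=["m_ratio_hat"], errors="ignore"),
                              on=["subject_id", "d_prime"], how="left")
    if demo is not None:
        subjects = subjects.merge(demo, on="subject_id", how="left",
                                  suffixes=(None, "_demo"))
    subjects.to_csv(out / "subjects.csv", index=False)

    # --- stage 5: analyses -------------------------------------------------
    toggles = dict(DEFAULT_ANALYSES) | dict(config.analyses)
    rows: list[dict] = []
    have_demo = demo is not None and "party" in subjects.columns
    equated_available = items is not None and bool(items["in_equated"].any())

    if toggles.get("demographics") and have_demo:
        rows += demographic_battery(subjects, "d_prime", "d_prime")
        rows += demographic_battery(subjects, "m_ratio", "m_ratio")

    if equated_available and (toggles.get("response_bias") or toggles.get("favorability")):
        eq_trials = subset_trials(trials, "equated_set", items=items)
        eq_trials = eq_trials[eq_trials["subject_id"].isin(subjects["subject_id"])]
        eq_est = _fit_mratio(eq_trials, replace(mcmc, seed=config.seed + 2))
        eq_est = eq_est[eq_est["m_ratio_hat"] >= 0]  # bias analyses drop negatives again
        eq = subjects[["subject_id"] + (["party", "strength", "age_bin", "age",
                                        "education", "gender"] if have_demo else [])]
        eq = eq.merge(eq_est.rename(columns={"m_ratio_hat": "m_ratio"}), on="subject_id")
        if toggles.get("response_bias") and have_demo:
            rows += _anova_rows(
                "c (equated): partisanship x strength",
                nstats.anova_2x2_between(eq["c"], eq["party"], eq["strength"],
                                         names=("partisanship", "strength")),
            )
            from .simulate import AGE_BINS

            rows += _anova_rows(
                "c (equated): age group",
                [nstats.anova_oneway(eq["c"], eq["age_bin"], order=list(AGE_BINS),
                                     effect="age_bin")],
            )
        if toggles.get("favorability") and have_demo:
            sides = {}
            for side, suffix in (("pro_democrat", "dem"), ("pro_republican", "rep")):
                side_trials = subset_trials(eq_trials, side)
                side_est = _fit_mratio(side_trials, replace(mcmc, seed=config.seed + 3))
                sides[suffix] = side_est.set_index("subject_id")
            fav = eq[["subject_id", "party"]].copy()
            for suffix, tbl in sides.items():
                fav[f"d_prime_{suffix}"] = fav["subject_id"].map(tbl["d_prime"])
                fav[f"c_{suffix}"] = fav["subject_id"].map(tbl["c"])
                fav[f"m_ratio_{suffix}"] = fav["subject_id"].map(tbl["m_ratio_hat"])
            for stub in ("d_prime", "c", "m_ratio"):
                rows += favorability_battery(fav, stub, f"{stub} (equated, by favorability)")
    elif toggles.get("response_bias") or toggles.get("favorability"):
        log.info("favorability/response-bias analyses skipped: no equated subset")

    if toggles.get("quartiles"):
        qa = nstats.quartile_analysis(subjects["d_prime"], subjects["m_ratio"])
        rows += _anova_rows("m_ratio by d_prime quartile", [qa["anova"]])
        rows.append(_ttest_row("m_ratio: bottom vs top d_prime quartile",
                               "Q1 - Q4", qa["bottom_vs_top"]))

    if toggles.get("splithalf"):
        halves = {}
        for name in ("even_index", "odd_index"):
            half = subset_trials(trials, name)
            half = half[half["subject_id"].isin(subjects["subject_id"])]
            halves[name] = _fit_mratio(half, replace(mcmc, seed=config.seed + 4)).rename(
                columns={"m_ratio_hat": "m_ratio"}
            )
        sh = nstats.splithalf_check(halves["even_index"], halves["odd_index"])
        rows += _anova_rows("splithalf: even d' quartiles vs odd m-ratio",
                            [sh["a_quartiles_vs_b_mratio"]])
        rows += _anova_rows("splithalf: odd d' quartiles vs even m-ratio",
                            [sh["b_quartiles_vs_a_mratio"]])

    results = nstats.results_to_frame(rows)
    results.to_csv(out / "analysis_results.csv", index=False)
    _write_report(results, out / "report.txt")
    manifest["stages"]["analysis"] = {"n_effects": int(len(results))}

    write_json(manifest, out / "manifest.json")
    return manifest


def _versions() -> dict:
    import pandas
    import scipy

    return {
        "newsmeta": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def _write_report(results: pd.DataFrame, path: Path) -> None:
    lines = ["newsmeta analysis report", "=" * 40]
    for _, r in results.iterrows():
        if np.isnan(r["df2"]) if isinstance(r["df2"], float) else False:
            lines.append(
                f"{r['analysis']} | {r['effect']}: stat={r['statistic']:.3f}, "
                f"p={r['p']:.4g}, effect size={r['effect_size']:.3f}"
            )
        else:
            lines.append(
                f"{r['analysis']} | {r['effect']}: F({r['df1']:.0f}, {r['df2']:.0f})="
                f"{r['statistic']:.2f}, p={r['p']:.4g}, np2={r['effect_size']:.3f}"
            )
    path.write_text("\n".join(lines) + "\n")
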