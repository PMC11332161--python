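"""The demographic statistical battery.

Wraps the standard routines (statsmodels type-III OLS ANOVA, pingouin
one-way/mixed ANOVA and t-tests, scipy rank correlation, noncentral-F power)
behind result containers carrying exactly the quantities reported in this
literature: F with numerator/denominator dfs, the error mean square, partial
eta squared, Welch t with Cohen's d and the 95% CI on the mean difference,
Spearman's rho, standardized regression betas, and an approximate JZS Bayes
factor for two-sample t-tests (inverted to favor the null, BF01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats
from statsmodels.stats.anova import anova_lm


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    MSE: float
    partial_eta_squared: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    ci95: tuple[float, float]
    cohens_d: float


def anova_2x2_between(
    dv: Sequence[float], factor_a: Sequence, factor_b: Sequence,
    names: tuple[str, str] = ("A", "B"),
) -> list[AnovaResult]:
    """2x2 between-subjects ANOVA (type-III SS, sum-to-zero contrasts).

    Returns the two main effects and the interaction.  Partial eta squared
    is SS_effect / (SS_effect + SS_error).
    """
    df = pd.DataFrame({"dv": np.asarray(dv, float), "fa": factor_a, "fb": factor_b})
    n_cells = df.groupby(["fa", "fb"]).ngroups
    if df["fa"].nunique() < 2 or df["fb"].nunique() < 2:
        raise ValueError("both factors need two levels")
    if n_cells < df["fa"].nunique() * df["fb"].nunique():
        raise ValueError("every cell of the design must be non-empty")
    model = smf.ols("dv ~ C(fa, Sum) * C(fb, Sum)", data=df).fit()
    table = anova_lm(model, typ=3)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = int(table.loc["Residual", "df"])
    mse = ss_err / df_err
    out = []
    labels = {
        "C(fa, Sum)": names[0],
        "C(fb, Sum)": names[1],
        "C(fa, Sum):C(fb, Sum)": f"{names[0]} x {names[1]}",
    }
    for row, label in labels.items():
        ss = float(table.loc[row, "sum_sq"])
        out.append(
            AnovaResult(
                effect=label,
                F=float(table.loc[row, "F"]),
                df_num=int(table.loc[row, "df"]),
                df_den=df_err,
                p=float(table.loc[row, "PR(>F)"]),
                MSE=mse,
                partial_eta_squared=ss / (ss + ss_err),
            )
        )
    return out


def anova_oneway(
    dv: Sequence[float], group: Sequence, order: Sequence | None = None,
    effect: str = "group",
) -> AnovaResult:
    """One-way ANOVA on an (ordered) factor; group order is preserved for
    reporting but does not change the omnibus F."""
    df = pd.DataFrame({"dv": np.asarray(dv, float), "group": list(group)})
    levels = list(order) if order is not None else sorted(df["group"].unique())
    present = [g for g in levels if (df["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("one-way ANOVA needs at least 2 non-empty groups")
    table = pg.anova(data=df, dv="dv", between="group", detailed=True)
    ss_eff = float(table.loc[0, "SS"])
    ss_err = float(table.loc[1, "SS"])
    df_err = int(table.loc[1, "DF"])
    return AnovaResult(
        effect=effect,
        F=float(table.loc[0, "F"]),
        df_num=int(table.loc[0, "DF"]),
        df_den=df_err,
        p=float(table.loc[0, "p_unc"]),
        MSE=ss_err / df_err,
        partial_eta_squared=ss_eff / (ss_eff + ss_err),
    )


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "dv",
    within: str = "item_type",
    subject: str = "subject_id",
    between: str = "party",
) -> list[AnovaResult]:
    """2x2 between-within ANOVA (e.g. partisanship x item favorability).

    The between effect is tested against subjects-within-groups, the within
    main effect and the interaction against the within x subjects-within-
    groups error term.  Requires both within-levels for every subject.
    """
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    if (counts < n_levels).any():
        bad = counts.index[counts < n_levels].tolist()
        raise ValueError(f"missing within-level for subjects: {bad[:5]}")
    table = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject, between=between)
    out = []
    for _, row in table.iterrows():
        if row["Source"] not in (between, within, "Interaction"):
            continue
        name = f"{between} x {within}" if row["Source"] == "Interaction" else str(row["Source"])
        ss = float(row["SS"])
        f_val = float(row["F"])
        ms_err = float(row["MS"]) / f_val if f_val > 0 else np.nan
        np2 = float(row["np2"])
        out.append(
            AnovaResult(
                effect=name,
                F=f_val,
                df_num=int(row["DF1"]),
                df_den=int(row["DF2"]),
                p=float(row["p_unc"]),
                MSE=ms_err,
                partial_eta_squared=np2,
            )
        )
    return out


def ttest(
    group_a: Sequence[float], group_b: Sequence[float], variant: str = "welch"
) -> TTestResult:
    """Two-sample t-test, Welch by default (pooled selectable).

    Cohen's d always uses the pooled standard deviation; the 95% CI is on
    the mean difference (a - b).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    res = pg.ttest(a, b, paired=False, correction=(variant == "welch"))
    row = res.iloc[0]
    t_val, dof = float(row["T"]), float(row["dof"])
    # CI on the mean difference at full precision (pingouin rounds its CI95)
    if variant == "welch":
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    else:
        sp = np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
            / (a.size + b.size - 2)
        )
        se = sp * np.sqrt(1 / a.size + 1 / b.size)
    half = stats.t.ppf(0.975, dof) * se
    diff = a.mean() - b.mean()
    return TTestResult(
        t=t_val,
        df=dof,
        p=float(row["p_val"]),
        ci95=(float(diff - half), float(diff + half)),
        cohens_d=float(row["cohen_d"]),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the
    t-approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("spearman needs paired data with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def regression_std(dv: Sequence[float], predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS on z-scored dv and predictors; standardized betas, SE, p and R^2.

    Binary predictors must already be numerically coded; they are then
    standardized like continuous ones.  The returned frame has one row per
    predictor plus an ``R2`` attribute in ``.attrs``.
    """
    y = np.asarray(dv, float)
    X = predictors.astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    Xz = (X - X.mean()) / X.std(ddof=1)
    if Xz.isna().any().any():
        const = X.columns[X.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant predictor columns: {const}")
    rank = np.linalg.matrix_rank(Xz.to_numpy())
    if rank < k:
        corr = Xz.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        raise ValueError(
            f"rank-deficient design; most collinear: {corr.index[pair[0]]}, {corr.columns[pair[1]]}"
        )
    yz = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    out = pd.DataFrame(
        {
            "beta": model.params.drop("const"),
            "se": model.bse.drop("const"),
            "p": model.pvalues.drop("const"),
        }
    )
    out.attrs["R2"] = float(model.rsquared)
    return out


def sensitivity_f(
    n_total: int, k_groups: int, alpha: float = 0.05, power: float = 0.95
) -> float:
    """Minimal detectable Cohen's f for a k-group fixed-effects ANOVA.

    Inverts noncentral-F power: finds f such that
    ``P(F' > F_crit; df1 = k-1, df2 = N-k, lambda = f^2 N) = power`` with
    F_crit the alpha critical value of the central F.  Bisection to 1e-6.
    """
    if n_total <= k_groups:
        raise ValueError("n_total must exceed k_groups")
    if not (0 < alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")
    df1, df2 = k_groups - 1, n_total - k_groups
    crit = stats.f.isf(alpha, df1, df2)

    def achieved(f: float) -> float:
        return float(stats.ncf.sf(crit, df1, df2, f * f * n_total))

    hi = 0.05
    while achieved(hi) < power:
        hi *= 2.0
        if hi > 64:
            raise ValueError("infeasible power request")
    return float(optimize.brentq(lambda f: achieved(f) - power, 1e-9, hi, xtol=1e-6))


def quartile_analysis(
    d_prime: Sequence[float], m_ratio: Sequence[float]
) -> dict:
    """Dunning–Kruger check: split subjects into d' quartiles and test
    whether m-ratio varies across them.

    Quartile membership is by rank (stable order for ties).  Returns the
    quartile labels, the one-way ANOVA of m-ratio on quartile, the
    per-quartile means, and the explicit bottom-vs-top t-test.
    """
    dp = np.asarray(d_prime, float)
    mr = np.asarray(m_ratio, float)
    n = dp.size
    if n < 8:
        raise ValueError("quartile analysis needs at least 8 subjects")
    order = np.argsort(dp, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    labels = np.minimum(ranks * 4 // n, 3) + 1  # quartile 1 = lowest d'
    anova = anova_oneway(mr, labels, order=[1, 2, 3, 4], effect="d_prime_quartile")
    bottom, top = mr[labels == 1], mr[labels == 4]
    contrast = ttest(bottom, top)
    means = {int(q): float(mr[labels == q].mean()) for q in (1, 2, 3, 4)}
    return {
        "quartile": labels,
        "anova": anova,
        "quartile_means": means,
        "bottom_vs_top": contrast,
    }


def splithalf_check(
    half_a: pd.DataFrame, half_b: pd.DataFrame
) -> dict:
    """Cross-half robustness: d' quartiles from one half against m-ratio
    from the other half, in both directions.

    Inputs are per-subject estimate tables (columns subject_id, d_prime,
    m_ratio) computed on even and odd trials respectively; estimation is the
    caller's job so this check composes with any estimator configuration.
    Also reports the split-half reliability of d' (Spearman across halves).
    """
    merged = half_a.merge(half_b, on="subject_id", suffixes=("_a", "_b"))
    if len(merged) < 8:
        raise ValueError("split-half check needs at least 8 subjects in both halves")
    a_to_b = quartile_analysis(merged["d_prime_a"], merged["m_ratio_b"])
    b_to_a = quartile_analysis(merged["d_prime_b"], merged["m_ratio_a"])
    rel, rel_p = spearman(merged["d_prime_a"], merged["d_prime_b"])
    return {
        "a_quartiles_vs_b_mratio": a_to_b["anova"],
        "b_quartiles_vs_a_mratio": b_to_a["anova"],
        "d_prime_reliability_rho": rel,
        "d_prime_reliability_p": rel_p,
        "n": len(merged),
    }


def jzs_bf01_ttest(
    group_a: Sequence[float], group_b: Sequence[float], r_scale: float = 0.707
) -> float:
    """Approximate Jeffreys–Zellner–Siow Bayes factor favoring the null
    for a two-sample t-test (default Cauchy scale 0.707).

    Approximate in the sense that it is the default-prior JZS integral for
    the t statistic, not a reproduction of any particular GUI package's
    ANOVA Bayes factors.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    res = stats.ttest_ind(a, b, equal_var=True)
    bf10 = pg.bayesfactor_ttest(float(res.statistic), a.size, b.size, paired=False, r=r_scale)
    return 1.0 / float(bf10)


def results_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Tidy export: one row per effect, fixed column order."""
    cols = [
        "analysis", "effect", "statistic", "df1", "df2",
        "estimate", "ci_low", "ci_high", "p", "effect_size",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)
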