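"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (statistics
module / explicit formulas / quadrature / grid search), not by calling the
code under test.
"""

from __future__ import annotations

import math
from statistics import NormalDist

import numpy as np
from scipy import integrate, optimize

_STD = NormalDist()


def z(p: float) -> float:
    return _STD.inv_cdf(p)


def phi_cdf(x: float) -> float:
    return _STD.cdf(x)


def gelman_rubin_reference(chains: np.ndarray) -> float:
    """Between/within variance formula, written out longhand."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    grand = means.mean()
    b = n / (m - 1) * sum((mu - grand) ** 2 for mu in means)
    w = sum(chains[j].var(ddof=1) for j in range(m)) / m
    var_plus = (n - 1) / n * w + b / n
    return math.sqrt(var_plus / w)


def metad_cell_probs_reference(
    d: float, c: float, md: float, tau_t: float, tau_f: float, p_true: float = 0.5
) -> np.ndarray:
    """(stimulus, response, confidence) probabilities via NormalDist only."""
    out = np.zeros((2, 2, 2))
    c2 = c * md / d
    for s, (mu1, mu2) in enumerate([(-d / 2, -md / 2), (d / 2, md / 2)]):
        ps = p_true if s == 1 else 1 - p_true
        p_resp_true = 1 - phi_cdf(c - mu1)
        denom_t = 1 - phi_cdf(c2 - mu2)
        p_high_t = (1 - phi_cdf(c2 + tau_t - mu2)) / denom_t if denom_t > 0 else 0.0
        denom_f = phi_cdf(c2 - mu2)
        p_high_f = phi_cdf(c2 - tau_f - mu2) / denom_f if denom_f > 0 else 0.0
        out[s, 1, 1] = ps * p_resp_true * p_high_t
        out[s, 1, 0] = ps * p_resp_true * (1 - p_high_t)
        out[s, 0, 1] = ps * (1 - p_resp_true) * p_high_f
        out[s, 0, 0] = ps * (1 - p_resp_true) * (1 - p_high_f)
    return out


def grid_search_metad_mle(
    counts: np.ndarray,
    d: float,
    c: float,
    grid: np.ndarray | None = None,
) -> float:
    """Brute-force maximum-likelihood meta-d' with type-1 fixed at (d, c).

    For each grid value of meta-d' the two type-2 criterion offsets are
    profiled out by separate 1-D likelihood maximizations (the "true"- and
    "false"-response cells depend only on their own offset).
    """
    if grid is None:
        grid = np.arange(-2.0, 4.0 + 1e-9, 0.01)
    counts = np.asarray(counts, float)
    n = counts.sum()
    p_true = counts[1].sum() / n

    def loglik(md: float) -> float:
        c2 = c * md / d

        def side_ll(tau: float, resp: int) -> float:
            total = 0.0
            for s, mu2 in ((0, -md / 2), (1, md / 2)):
                if resp == 1:
                    den = 1 - phi_cdf(c2 - mu2)
                    ph = (1 - phi_cdf(c2 + tau - mu2)) / den if den > 1e-300 else 0.0
                else:
                    den = phi_cdf(c2 - mu2)
                    ph = phi_cdf(c2 - tau - mu2) / den if den > 1e-300 else 0.0
                ph = min(max(ph, 1e-300), 1 - 1e-12)
                total += counts[s, resp, 1] * math.log(ph)
                total += counts[s, resp, 0] * math.log(1 - ph)
            return total

        best = 0.0
        for resp in (0, 1):
            r = optimize.minimize_scalar(
                lambda tau: -side_ll(tau, resp), bounds=(1e-3, 8.0), method="bounded"
            )
            best += -r.fun
        return best

    lls = np.array([loglik(md) for md in grid])
    return float(grid[int(np.argmax(lls))])


def jzs_bf10_reference(t: float, nx: int, ny: int, r: float = 0.707) -> float:
    """Two-sample JZS Bayes factor by direct quadrature over the g prior."""
    n_eff = nx * ny / (nx + ny)
    nu = nx + ny - 2

    def integrand(g: float) -> float:
        a = (1 + n_eff * g * r**2) ** -0.5
        b = (1 + t**2 / ((1 + n_eff * g * r**2) * nu)) ** (-(nu + 1) / 2)
        prior = (2 * math.pi) ** -0.5 * g ** (-1.5) * math.exp(-1 / (2 * g))
        return a * b * prior

    num = integrate.quad(integrand, 0, np.inf, limit=200)[0]
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


def welch_ttest_reference(a: np.ndarray, b: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Welch t, Welch–Satterthwaite df, and the 95% CI on mean(a) - mean(b)."""
    from scipy import stats as sps

    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    tcrit = sps.t.ppf(0.975, df)
    diff = a.mean() - b.mean()
    half = tcrit * math.sqrt(se2)
    return t, df, (diff - half, diff + half)


def spearman_reference(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks, computed by hand."""

    def avg_ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
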