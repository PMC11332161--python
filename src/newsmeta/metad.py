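"""Bayesian estimation of metacognitive efficiency (meta-d' and m-ratio).

meta-d' is the type-1 sensitivity a subject *would need*, under the
equal-variance Gaussian SDT model, to produce their observed confidence
(type-2) performance if they were metacognitively ideal.  Dividing by the
subject's actual d' gives the m-ratio, a measure of metacognitive efficiency
that controls for task performance; an ideal observer has m-ratio 1.

The model here follows the Maniscalco & Lau construction with binarized
confidence (two type-2 criteria, one per response side).  Type-1 response
probabilities come from the subject's real (d', c); confidence probabilities,
conditional on stimulus and response, come from a meta-level observer with
sensitivity meta-d' whose criterion sits at the same *relative* position,
c_meta = c * meta-d'/d'.  The eight (stimulus x response x confidence) cell
counts are multinomial, and d', c, meta-d' and the two type-2 criterion
offsets are sampled jointly by MCMC (three chains by default, Gelman-Rubin
R-hat reported per parameter).  Cells with zero counts need no ad-hoc
padding: they simply contribute nothing to the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._mcmc import gelman_rubin, sample_rwm
from .sdt import Type2Counts, compute_type1_estimates

PARAM_NAMES = ("d_prime", "c", "meta_d", "tau_true", "tau_false")

#: R-hat above this triggers the convergence warning contract
RHAT_LIMIT = 1.01

_EPS = 1e-12


@dataclass(frozen=True)
class MetaDPriors:
    """Priors for the subject-level model.

    Defaults follow the estimation framework the model is drawn from, which
    specifies its normal priors in JAGS precision form — Normal(0, 0.5) and
    Normal(0, 2) there mean precisions 0.5 and 2, i.e. sd sqrt(2) for d' and
    meta-d' (the latter centred on d') and sd 1/sqrt(2) for c.  The type-2
    criterion offsets, which that framework leaves unstated, get weakly
    informative half-normal(sd 2) priors, one per response side.
    """

    d_prime_sd: float = math.sqrt(2.0)
    c_sd: float = math.sqrt(0.5)
    meta_d_sd: float = math.sqrt(2.0)
    tau_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("d_prime_sd", "c_sd", "meta_d_sd", "tau_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def broadened(self, factor: float) -> "MetaDPriors":
        """All sds multiplied by ``factor`` (e.g. 100 for near-flat priors)."""
        return MetaDPriors(
            d_prime_sd=self.d_prime_sd * factor,
            c_sd=self.c_sd * factor,
            meta_d_sd=self.meta_d_sd * factor,
            tau_sd=self.tau_sd * factor,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration: 3 chains of 10,000 samples, first 2,000 warm-up."""

    n_chains: int = 3
    n_samples: int = 10_000
    n_warmup: int = 2_000
    seed: int = 0
    min_trials: int = 20

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (R-hat needs multiple chains)")
        if self.n_warmup >= self.n_samples:
            raise ValueError("n_warmup must be < n_samples")


@dataclass
class MetaDFit:
    """Posterior summary for one subject."""

    subject_id: str
    meta_d_hat: float
    d_prime_hat: float
    c_hat: float
    tau_true_hat: float
    tau_false_hat: float
    m_ratio_hat: float
    rhat: dict[str, float]
    n_trials: int
    accept_rate: float
    draws: np.ndarray | None = None  # (n_kept, n_chains, 5)

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.rhat_max < RHAT_LIMIT

    def to_record(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "meta_d_hat": self.meta_d_hat,
            "d_prime_hat": self.d_prime_hat,
            "c_hat": self.c_hat,
            "m_ratio_hat": self.m_ratio_hat,
            "rhat_max": self.rhat_max,
            "n_trials": self.n_trials,
            "converged": self.converged,
        }


def m_ratio(meta_d: float, d_prime: float) -> float:
    """Metacognitive efficiency meta-d'/d'.  Undefined at d' = 0."""
    if d_prime == 0:
        raise ValueError("undefined m-ratio: d_prime is 0")
    return meta_d / d_prime


def rhat(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor (see :mod:`._mcmc`)."""
    return gelman_rubin(chains)


# ---------------------------------------------------------------------------
# model probabilities
# ---------------------------------------------------------------------------


def _cell_probs(
    d: np.ndarray,
    c: np.ndarray,
    md: np.ndarray,
    tau_t: np.ndarray,
    tau_f: np.ndarray,
    p_true: np.ndarray | float = 0.5,
) -> np.ndarray:
    """Vectorized 8-cell probabilities, output shape ``(*broadcast, 2, 2, 2)``.

    Index order is (stimulus, response, confidence): stimulus 0 = false_news,
    1 = true_news; response 0 = "false", 1 = "true"; confidence 0 = low,
    1 = high.
    """
    d, c, md, tau_t, tau_f = np.broadcast_arrays(d, c, md, tau_t, tau_f)
    p_true = np.broadcast_to(p_true, d.shape)

    # type-1 response probabilities from the real observer
    p_r1 = np.stack([ndtr(-d / 2 - c), ndtr(d / 2 - c)], axis=-1)  # (.., s)

    # meta-level observer: criterion at the same relative position
    ratio = md / d
    c2 = c * ratio
    mu2 = np.stack([-md / 2, md / 2], axis=-1)  # (.., s)
    c2e = c2[..., None]
    # P(high | r = true, s): upper tail beyond c2 + tau_true, normalized by
    # the meta-level probability of responding true
    num_t = ndtr(mu2 - (c2e + tau_t[..., None]))
    den_t = ndtr(mu2 - c2e)
    p_high_r1 = num_t / np.clip(den_t, _EPS, None)
    # P(high | r = false, s): lower tail beyond c2 - tau_false
    num_f = ndtr((c2e - tau_f[..., None]) - mu2)
    den_f = ndtr(c2e - mu2)
    p_high_r0 = num_f / np.clip(den_f, _EPS, None)
    p_high_r1 = np.clip(p_high_r1, 0.0, 1.0)
    p_high_r0 = np.clip(p_high_r0, 0.0, 1.0)

    p_s = np.stack([1.0 - p_true, p_true], axis=-1)  # (.., s)
    out = np.empty((*d.shape, 2, 2, 2))
    out[..., :, 1, 1] = p_s * p_r1 * p_high_r1
    out[..., :, 1, 0] = p_s * p_r1 * (1.0 - p_high_r1)
    out[..., :, 0, 1] = p_s * (1.0 - p_r1) * p_high_r0
    out[..., :, 0, 0] = p_s * (1.0 - p_r1) * (1.0 - p_high_r0)
    return out


def type2_model_probabilities(
    meta_d: float,
    d_prime: float,
    c: float,
    tau_true: float,
    tau_false: float,
    p_true: float = 0.5,
) -> np.ndarray:
    """Predicted probabilities of the eight type-2 cells.

    Returns a ``(2, 2, 2)`` array indexed (stimulus, response, confidence)
    as in :class:`newsmeta.sdt.Type2Counts`; entries sum to 1.
    """
    if tau_true <= 0 or tau_false <= 0:
        raise ValueError("type-2 criterion offsets must be positive")
    if d_prime == 0:
        raise ValueError("d_prime must be nonzero")
    probs = _cell_probs(
        np.float64(d_prime),
        np.float64(c),
        np.float64(meta_d),
        np.float64(tau_true),
        np.float64(tau_false),
        p_true,
    )
    if not np.all(np.isfinite(probs)):
        raise ValueError("degenerate cell probabilities for these parameters")
    return probs


def _log_likelihood(theta: np.ndarray, counts: np.ndarray, p_true: np.ndarray) -> np.ndarray:
    """Multinomial log likelihood; theta ``(*lead, 5)``, counts ``(*lead?, 2,2,2)``."""
    d, c, md = theta[..., 0], theta[..., 1], theta[..., 2]
    tau_t, tau_f = theta[..., 3], theta[..., 4]
    probs = _cell_probs(d, c, md, tau_t, tau_f, p_true)
    return np.sum(counts * np.log(np.clip(probs, 1e-300, None)), axis=(-3, -2, -1))


def _log_prior(theta: np.ndarray, priors: MetaDPriors) -> np.ndarray:
    d, c, md = theta[..., 0], theta[..., 1], theta[..., 2]
    tau_t, tau_f = theta[..., 3], theta[..., 4]
    lp = (
        -0.5 * (d / priors.d_prime_sd) ** 2
        - 0.5 * (c / priors.c_sd) ** 2
        - 0.5 * ((md - d) / priors.meta_d_sd) ** 2
        - 0.5 * (tau_t / priors.tau_sd) ** 2
        - 0.5 * (tau_f / priors.tau_sd) ** 2
    )
    bad = (tau_t <= 0) | (tau_f <= 0) | (np.abs(d) < 1e-4)
    return np.where(bad, -np.inf, lp)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _initial_states(
    counts: np.ndarray,
    n_chains: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overdispersed chain starts around the type-1 point estimates.

    counts: (n_subjects, 2, 2, 2) -> (n_subjects, n_chains, 5)
    """
    n_sub = counts.shape[0]
    t1 = counts.sum(axis=3)
    n_true = t1[:, 1].sum(axis=1)
    n_false = t1[:, 0].sum(axis=1)
    hr = np.clip(t1[:, 1, 1] / n_true, 1.0 / (2 * n_true), 1 - 1.0 / (2 * n_true))
    fr = np.clip(t1[:, 0, 1] / n_false, 1.0 / (2 * n_false), 1 - 1.0 / (2 * n_false))
    d0 = ndtri(hr) - ndtri(fr)
    d0 = np.where(np.abs(d0) < 0.05, 0.05, d0)
    c0 = -0.5 * (ndtri(hr) + ndtri(fr))
    x0 = np.empty((n_sub, n_chains, 5))
    x0[..., 0] = d0[:, None] + 0.2 * rng.standard_normal((n_sub, n_chains))
    x0[..., 0] = np.where(np.abs(x0[..., 0]) < 0.05, 0.05, x0[..., 0])
    x0[..., 1] = c0[:, None] + 0.15 * rng.standard_normal((n_sub, n_chains))
    x0[..., 2] = x0[..., 0] * np.exp(0.3 * rng.standard_normal((n_sub, n_chains)))
    x0[..., 3] = np.abs(0.5 + 0.2 * rng.standard_normal((n_sub, n_chains))) + 0.05
    x0[..., 4] = np.abs(0.5 + 0.2 * rng.standard_normal((n_sub, n_chains))) + 0.05
    return x0


def fit_metad_cohort(
    counts: Sequence[Type2Counts],
    priors: MetaDPriors | None = None,
    config: MCMCConfig | None = None,
    subject_ids: Sequence[str] | None = None,
    keep_draws: bool = False,
) -> list[MetaDFit]:
    """Fit the subject-level model to many subjects at once.

    All subjects share one vectorized sampler run (independent targets), so
    fitting a cohort costs little more than fitting one subject.
    """
    priors = priors or MetaDPriors()
    config = config or MCMCConfig()
    if subject_ids is None:
        subject_ids = [f"s{i:04d}" for i in range(len(counts))]
    if len(subject_ids) != len(counts):
        raise ValueError("subject_ids and counts length mismatch")
    arr = np.stack([np.asarray(c.counts, dtype=float) for c in counts])  # (S,2,2,2)
    n_trials = arr.sum(axis=(1, 2, 3))
    if np.any(n_trials < config.min_trials):
        bad = [subject_ids[i] for i in np.nonzero(n_trials < config.min_trials)[0]]
        raise ValueError(f"too few trials (<{config.min_trials}) for subjects: {bad}")
    n_true = arr[:, 1].sum(axis=(1, 2))
    p_true = (n_true / n_trials)[:, None]  # broadcast over chains

    rng = np.random.default_rng(config.seed)
    x0 = _initial_states(arr, config.n_chains, rng)
    counts_b = arr[:, None]  # (S, 1, 2, 2, 2) broadcasting over chains

    def log_post(theta: np.ndarray) -> np.ndarray:
        return _log_likelihood(theta, counts_b, p_true) + _log_prior(theta, priors)

    # clip -inf starts back into support (tau jitter can't go negative here,
    # but meta_d near-zero d is possible for d0 ~ 0 subjects)
    lp0 = log_post(x0)
    if np.any(~np.isfinite(lp0)):
        x0[~np.isfinite(lp0)] = np.array([1.0, 0.0, 1.0, 0.5, 0.5])

    init_scales = np.array([0.15, 0.1, 0.25, 0.15, 0.15])
    draws, acc = sample_rwm(
        log_post,
        x0,
        n_samples=config.n_samples,
        n_warmup=config.n_warmup,
        rng=rng,
        init_scales=init_scales,
        pool_axis=1,  # chains of one subject share a posterior
    )
    # draws: (n_keep, S, C, 5)
    means = draws.mean(axis=(0, 2))  # (S, 5)
    fits: list[MetaDFit] = []
    for i, sid in enumerate(subject_ids):
        rh = {
            name: gelman_rubin(draws[:, i, :, j].T)
            for j, name in enumerate(PARAM_NAMES)
        }
        d_hat = float(means[i, 0])
        md_hat = float(means[i, 2])
        fits.append(
            MetaDFit(
                subject_id=str(sid),
                meta_d_hat=md_hat,
                d_prime_hat=d_hat,
                c_hat=float(means[i, 1]),
                tau_true_hat=float(means[i, 3]),
                tau_false_hat=float(means[i, 4]),
                m_ratio_hat=m_ratio(md_hat, d_hat),
                rhat=rh,
                n_trials=int(n_trials[i]),
                accept_rate=float(acc[i].mean()),
                draws=draws[:, i].copy() if keep_draws else None,
            )
        )
    return fits


def fit_metad_subject(
    counts: Type2Counts,
    priors: MetaDPriors | None = None,
    config: MCMCConfig | None = None,
    subject_id: str = "subject",
    keep_draws: bool = True,
) -> MetaDFit:
    """Fit the non-hierarchical Bayesian meta-d' model for one subject."""
    return fit_metad_cohort(
        [counts], priors, config, subject_ids=[subject_id], keep_draws=keep_draws
    )[0]


def fit_metad_map(
    counts: Type2Counts,
    priors: MetaDPriors | None = None,
    fixed_type1: tuple[float, float] | None = None,
    broaden: float = 1.0,
) -> dict[str, float]:
    """Posterior mode (MAP) by direct optimization.

    With ``fixed_type1=(d_prime, c)`` only (meta_d, tau_true, tau_false) are
    optimized — the mode against which the brute-force maximum-likelihood
    grid search is compared.  ``broaden`` multiplies all prior sds (a large
    factor makes the mode effectively the MLE).
    """
    priors = (priors or MetaDPriors()).broadened(broaden)
    arr = np.asarray(counts.counts, dtype=float)
    n = arr.sum()
    p_true = arr[1].sum() / n

    if fixed_type1 is None:
        est = compute_type1_estimates(counts.type1())
        x0 = np.array([max(est.d_prime, 0.05), est.c, max(est.d_prime, 0.05), 0.5, 0.5])
        free = np.arange(5)
    else:
        d_fix, c_fix = fixed_type1
        if abs(d_fix) < 1e-4:
            raise ValueError("fixed d_prime too close to 0")
        x0 = np.array([d_fix, c_fix, max(d_fix, 0.05), 0.5, 0.5])
        free = np.array([2, 3, 4])

    def neg_log_post(v: np.ndarray) -> float:
        theta = x0.copy()
        theta[free] = v
        lp = _log_likelihood(theta, arr, p_true) + _log_prior(theta, priors)
        return -float(lp) if np.isfinite(lp) else 1e12

    bounds_all = [(-6, 6), (-4, 4), (-6, 6), (1e-3, 8.0), (1e-3, 8.0)]
    res = optimize.minimize(
        neg_log_post,
        x0[free],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
    )
    theta = x0.copy()
    theta[free] = res.x
    theta[3] = abs(theta[3])
    theta[4] = abs(theta[4])
    # keep within the box used by the grid oracle
    for j, (lo, hi) in enumerate(bounds_all):
        theta[j] = min(max(theta[j], lo), hi)
    return dict(zip(PARAM_NAMES, map(float, theta)))


# ---------------------------------------------------------------------------
# hierarchical model
# ---------------------------------------------------------------------------


@dataclass
class GroupMetaDFit:
    """Hierarchical fit: subjects shrink toward a group log-m-ratio mean."""

    group_m_ratio_hat: float
    group_m_ratio_ci95: tuple[float, float]
    mu_log_m_ratio_hat: float
    sigma_log_m_ratio_hat: float
    subject_m_ratio_hat: np.ndarray
    subject_meta_d_hat: np.ndarray
    subject_d_prime_hat: np.ndarray
    rhat: dict[str, float]
    n_subjects: int

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.rhat_max < RHAT_LIMIT


def fit_metad_group(
    counts: Sequence[Type2Counts],
    config: MCMCConfig | None = None,
    priors: MetaDPriors | None = None,
) -> GroupMetaDFit:
    """Hierarchical meta-d': subject log-m-ratios ~ Normal(mu, sigma).

    Subject-level parameters are (d', c, log m-ratio, tau_true, tau_false)
    with meta-d' = exp(log m-ratio) * d'; the group level samples mu (normal
    prior, sd 1) and sigma (half-normal prior, sd 1).  Sampling alternates a
    vectorized Metropolis sweep over the (conditionally independent) subject
    blocks with a conjugate draw of mu and a Metropolis step on log sigma.
    The group m-ratio summary reported is exp(mu), with its posterior mean
    and central 95% credible interval.
    """
    if len(counts) < 2:
        raise ValueError("hierarchical fit requires a group (>= 2 subjects)")
    config = config or MCMCConfig()
    priors = priors or MetaDPriors()
    S, C = len(counts), config.n_chains
    arr = np.stack([np.asarray(ct.counts, dtype=float) for ct in counts])  # (S,2,2,2)
    n_trials = arr.sum(axis=(1, 2, 3))
    p_true = arr[:, 1].sum(axis=(1, 2)) / n_trials  # (S,)

    rng = np.random.default_rng(config.seed)

    # subject state: (C, S, 5) = (d, c, log_mr, tau_t, tau_f)
    base = _initial_states(arr, C, rng)  # (S, C, 5)
    x = np.transpose(base, (1, 0, 2)).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        log_mr0 = np.log(np.clip(x[..., 2] / np.where(x[..., 0] == 0, 1, x[..., 0]), 0.2, 3.0))
    x[..., 2] = np.where(np.isfinite(log_mr0), log_mr0, 0.0)
    x[..., 0] = np.abs(x[..., 0]) + 0.05  # hierarchical model keeps d' > 0
    mu = x[..., 2].mean(axis=1)  # (C,)
    log_sigma = np.full(C, np.log(0.3))

    counts_b = arr[None]  # (1, S, 2, 2, 2)
    p_true_b = p_true[None]

    def subject_logpost(state: np.ndarray, mu_: np.ndarray, sig_: np.ndarray) -> np.ndarray:
        d, c, log_mr = state[..., 0], state[..., 1], state[..., 2]
        tau_t, tau_f = state[..., 3], state[..., 4]
        md = np.exp(log_mr) * d
        theta = np.stack([d, c, md, tau_t, tau_f], axis=-1)
        ll = _log_likelihood(theta, counts_b, p_true_b)
        lp = (
            -0.5 * (d / priors.d_prime_sd) ** 2
            - 0.5 * (c / priors.c_sd) ** 2
            - 0.5 * ((log_mr - mu_[:, None]) / sig_[:, None]) ** 2
            - np.log(sig_[:, None])
            - 0.5 * (tau_t / priors.tau_sd) ** 2
            - 0.5 * (tau_f / priors.tau_sd) ** 2
        )
        bad = (tau_t <= 0) | (tau_f <= 0) | (d < 1e-3)
        return ll + np.where(bad, -np.inf, lp)

    scales = np.broadcast_to(np.array([0.15, 0.1, 0.2, 0.15, 0.15]), x.shape).copy()
    log_step = np.zeros((C, S))
    sig_step = np.full(C, -1.0)
    target = 0.3

    n_keep = config.n_samples - config.n_warmup
    keep_mu = np.empty((n_keep, C))
    keep_sigma = np.empty((n_keep, C))
    keep_subj = np.zeros((C, S, 5))  # running sum for posterior means
    keep_mr = np.zeros((C, S))
    keep_md = np.zeros((C, S))

    lp = subject_logpost(x, mu, np.exp(log_sigma))
    for t in range(config.n_samples):
        sig = np.exp(log_sigma)
        # 1) subject blocks, all in parallel
        z = rng.standard_normal(x.shape)
        prop = x + np.exp(log_step)[..., None] * scales * z
        lp_prop = subject_logpost(prop, mu, sig)
        accept = np.log(rng.random((C, S))) < lp_prop - lp
        x[accept] = prop[accept]
        lp = np.where(accept, lp_prop, lp)
        # 2) mu | log_mr, sigma  (normal prior N(0, 1))
        prec = S / sig**2 + 1.0
        mean = (x[..., 2].sum(axis=1) / sig**2) / prec
        mu = mean + rng.standard_normal(C) / np.sqrt(prec)
        # 3) sigma via Metropolis on log sigma (half-normal(1) prior)
        prop_ls = log_sigma + np.exp(sig_step) * rng.standard_normal(C)
        def sigma_target(ls: np.ndarray) -> np.ndarray:
            s_ = np.exp(ls)
            resid = x[..., 2] - mu[:, None]
            return (
                -S * ls
                - 0.5 * (resid**2).sum(axis=1) / s_**2
                - 0.5 * s_**2
                + ls  # Jacobian of the log transform
            )
        acc_s = np.log(rng.random(C)) < sigma_target(prop_ls) - sigma_target(log_sigma)
        log_sigma = np.where(acc_s, prop_ls, log_sigma)
        lp = subject_logpost(x, mu, np.exp(log_sigma))

        if t < config.n_warmup:
            gamma = 2.0 / (t + 10.0) ** 0.7
            log_step += gamma * (accept.astype(float) - target)
            sig_step += gamma * (acc_s.astype(float) - target)
        else:
            i = t - config.n_warmup
            keep_mu[i] = mu
            keep_sigma[i] = np.exp(log_sigma)
            keep_subj += x
            keep_mr += np.exp(x[..., 2])
            keep_md += np.exp(x[..., 2]) * x[..., 0]

    group_draws = np.exp(keep_mu)  # (n_keep, C)
    flat = group_draws.ravel()
    subj_means = keep_subj / n_keep
    rh = {
        "mu_log_m_ratio": gelman_rubin(keep_mu.T),
        "sigma_log_m_ratio": gelman_rubin(keep_sigma.T),
    }
    return GroupMetaDFit(
        group_m_ratio_hat=float(flat.mean()),
        group_m_ratio_ci95=(float(np.quantile(flat, 0.025)), float(np.quantile(flat, 0.975))),
        mu_log_m_ratio_hat=float(keep_mu.mean()),
        sigma_log_m_ratio_hat=float(keep_sigma.mean()),
        subject_m_ratio_hat=(keep_mr / n_keep).mean(axis=0),
        subject_meta_d_hat=(keep_md / n_keep).mean(axis=0),
        subject_d_prime_hat=subj_means[..., 0].mean(axis=0),
        rhat=rh,
        n_subjects=S,
    )
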