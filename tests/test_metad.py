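"""The meta-d' measurement model and its Bayesian fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import newsmeta as nm
from newsmeta.sdt import Type2Counts

from conftest import balanced_items
from oracles import metad_cell_probs_reference


def counts_from_observer(d, c, sigma, n_per_class, rng, tau=(0.5, 1.5)) -> Type2Counts:
    obs = nm.ObserverParams(d, c, sigma, tau)
    trials = nm.simulate_trials(obs, balanced_items(n_per_class), rng, "s")
    return nm.classify_trials(trials)[1]


class TestModelProbabilities:
    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0.2, 3.0),
        st.floats(-1.0, 1.0),
        st.floats(-2.0, 3.0),
        st.floats(0.05, 3.0),
        st.floats(0.05, 3.0),
    )
    def test_cells_are_a_probability_distribution(self, d, c, md, tt, tf):
        p = nm.type2_model_probabilities(md, d, c, tt, tf)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_formula(self):
        p = nm.type2_model_probabilities(0.8, 1.5, 0.25, 0.6, 0.9)
        ref = metad_cell_probs_reference(1.5, 0.25, 0.8, 0.6, 0.9)
        np.testing.assert_allclose(p, ref, atol=1e-12)

    def test_ideal_metacognition_confidence_is_informative(self):
        """meta-d' = d': type-2 hit rate strictly exceeds type-2 FA rate."""
        p = nm.type2_model_probabilities(1.4, 1.4, 0.3, 0.5, 0.5)
        correct = p[1, 1] + p[0, 0]
        wrong = p[0, 1] + p[1, 0]
        t2_hr = correct[1] / correct.sum()
        t2_far = wrong[1] / wrong.sum()
        assert t2_hr > t2_far

    def test_zero_metad_confidence_carries_no_information(self):
        p = nm.type2_model_probabilities(0.0, 1.5, 0.2, 0.5, 0.5)
        for r in (0, 1):  # per response side, P(high) identical across stimuli
            ph_s0 = p[0, r, 1] / p[0, r].sum()
            ph_s1 = p[1, r, 1] / p[1, r].sum()
            assert ph_s0 == pytest.approx(ph_s1, abs=1e-12)

    def test_monte_carlo_oracle_when_meta_equals_type1(self):
        """With meta-d' = d' the model is a single-evidence observer, so the
        cells can be simulated directly: x ~ N(+-d/2, 1), answer true iff
        x > c, high confidence beyond the offset criterion."""
        d, c, tau = 1.0, 0.0, 0.5
        p = nm.type2_model_probabilities(d, d, c, tau, tau)
        rng = np.random.default_rng(123)
        n = 10_000_000
        emp = np.zeros((2, 2, 2))
        for s, mu in ((0, -d / 2), (1, d / 2)):
            x = rng.normal(mu, 1.0, n // 2)
            r = (x > c).astype(int)
            high = np.where(r == 1, x > c + tau, x < c - tau).astype(int)
            for ri in (0, 1):
                for hi in (0, 1):
                    emp[s, ri, hi] = np.sum((r == ri) & (high == hi)) / n
        np.testing.assert_allclose(p, emp, atol=1.5e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nm.type2_model_probabilities(1.0, 1.0, 0.0, -0.5, 0.5)
        with pytest.raises(ValueError, match="nonzero"):
            nm.type2_model_probabilities(1.0, 0.0, 0.0, 0.5, 0.5)


class TestMRatio:
    def test_ideal_observer_value(self):
        assert nm.m_ratio(1.8, 1.8) == 1.0

    def test_arithmetic(self):
        assert nm.m_ratio(0.9, 1.8) == pytest.approx(0.5)

    def test_negative_meta_d_passes_through_for_downstream_exclusion(self):
        assert nm.m_ratio(-0.2, 1.0) == pytest.approx(-0.2)

    def test_zero_d_prime_is_undefined(self):
        with pytest.raises(ValueError, match="undefined m-ratio"):
            nm.m_ratio(1.0, 0.0)


class TestConfigValidation:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="n_chains"):
            nm.MCMCConfig(n_chains=1)

    def test_warmup_must_be_shorter_than_run(self):
        with pytest.raises(ValueError, match="n_warmup"):
            nm.MCMCConfig(n_samples=100, n_warmup=100)

    def test_priors_must_be_positive(self):
        with pytest.raises(ValueError):
            nm.MetaDPriors(d_prime_sd=0.0)

    def test_too_few_trials_rejected(self, rng, reduced_mcmc):
        c = counts_from_observer(1.5, 0.0, 0.3, 5, rng)
        with pytest.raises(ValueError, match="too few trials"):
            nm.fit_metad_subject(c, config=reduced_mcmc)


class TestSubjectFit:
    def test_fit_reports_all_diagnostics(self, rng, reduced_mcmc):
        c = counts_from_observer(1.6, 0.1, 0.4, 70, rng)
        fit = nm.fit_metad_subject(c, config=reduced_mcmc)
        assert set(fit.rhat) == {"d_prime", "c", "meta_d", "tau_true", "tau_false"}
        assert fit.m_ratio_hat == pytest.approx(fit.meta_d_hat / fit.d_prime_hat)
        assert fit.draws is not None and fit.draws.shape[1] == 3
        rec = fit.to_record()
        assert {"subject_id", "meta_d_hat", "m_ratio_hat", "rhat_max",
                "converged", "n_trials"} <= set(rec)

    def test_zero_count_cells_need_no_padding(self, reduced_mcmc):
        # every response maximally confident: all low-confidence cells empty
        counts = Type2Counts(np.array([[[0, 20], [0, 10]], [[0, 8], [0, 25]]]))
        fit = nm.fit_metad_subject(counts, config=reduced_mcmc)
        assert np.isfinite(fit.meta_d_hat)
        assert np.isfinite(fit.m_ratio_hat)

    def test_heavy_meta_noise_lowers_fitted_m_ratio(self, rng, reduced_mcmc):
        quiet, noisy = [], []
        for i in range(25):
            quiet.append(counts_from_observer(1.8, 0.1, 0.1, 70, rng))
            noisy.append(counts_from_observer(1.8, 0.1, 1.8, 70, rng))
        fits_q = nm.fit_metad_cohort(quiet, config=reduced_mcmc)
        fits_n = nm.fit_metad_cohort(noisy, config=reduced_mcmc)
        mean_q = np.mean([f.m_ratio_hat for f in fits_q])
        mean_n = np.mean([f.m_ratio_hat for f in fits_n])
        assert mean_n < mean_q - 0.15

    def test_matched_efficiency_is_scale_free(self, rng, reduced_mcmc):
        """Observers with the same c' and the same population m-ratio but
        different d' produce indistinguishable fitted m-ratio means."""
        lo_sig = nm.calibrate_meta_noise(0.8, nm.ObserverParams(1.2, 0.12))
        hi_sig = nm.calibrate_meta_noise(0.8, nm.ObserverParams(2.0, 0.20))
        lo = [counts_from_observer(1.2, 0.12, lo_sig, 70, rng) for _ in range(40)]
        hi = [counts_from_observer(2.0, 0.20, hi_sig, 70, rng) for _ in range(40)]
        mean_lo = np.mean([f.m_ratio_hat for f in nm.fit_metad_cohort(lo, config=reduced_mcmc)])
        mean_hi = np.mean([f.m_ratio_hat for f in nm.fit_metad_cohort(hi, config=reduced_mcmc)])
        assert mean_lo == pytest.approx(mean_hi, abs=0.12)


class TestHierarchicalFit:
    def test_requires_a_group(self, reduced_mcmc):
        c = Type2Counts(np.full((2, 2, 2), 5))
        with pytest.raises(ValueError, match="group"):
            nm.fit_metad_group([c], config=reduced_mcmc)

    def test_identical_groups_have_overlapping_intervals(self, rng, equated_set):
        cfg = nm.MCMCConfig(n_samples=2500, n_warmup=1000, seed=11)
        obs = nm.ObserverParams(1.8, 0.1, 0.5)
        groups = []
        for _ in range(2):
            counts = [
                nm.classify_trials(nm.simulate_trials(obs, equated_set.items, rng, "s"))[1]
                for _ in range(12)
            ]
            groups.append(nm.fit_metad_group(counts, config=cfg))
        (lo1, hi1), (lo2, hi2) = groups[0].group_m_ratio_ci95, groups[1].group_m_ratio_ci95
        assert max(lo1, lo2) < min(hi1, hi2)  # intervals overlap

    def test_shrinkage_beats_independent_fits_at_32_trials(self, rng):
        """At 32 trials/subject the hierarchical subject estimates should sit
        closer to the common truth than the non-hierarchical ones (RMSE)."""
        items = balanced_items(16)  # 32 trials
        obs = nm.ObserverParams(1.8, 0.1, 0.4)
        truth_md = nm.effective_meta_d(obs)
        counts = [
            nm.classify_trials(nm.simulate_trials(obs, items, rng, f"s{i}"))[1]
            for i in range(20)
        ]
        cfg = nm.MCMCConfig(n_samples=2500, n_warmup=1000, seed=3, min_trials=20)
        hier = nm.fit_metad_group(counts, config=cfg)
        indiv = nm.fit_metad_cohort(counts, config=cfg)
        rmse_h = np.sqrt(np.mean((hier.subject_meta_d_hat - truth_md) ** 2))
        rmse_i = np.sqrt(np.mean((np.array([f.meta_d_hat for f in indiv]) - truth_md) ** 2))
        assert rmse_h < rmse_i

    def test_group_interval_covers_common_truth(self, rng, equated_set):
        """Replicate groups of identical observers: the 95% interval should
        cover the population m-ratio nearly always."""
        obs = nm.ObserverParams(1.8, 0.1, 0.5)
        truth = nm.effective_m_ratio(obs)
        cfg = nm.MCMCConfig(n_samples=2500, n_warmup=1000, seed=29)
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            counts = [
                nm.classify_trials(nm.simulate_trials(obs, equated_set.items, rng, "s"))[1]
                for _ in range(12)
            ]
            fit = nm.fit_metad_group(counts, config=cfg)
            lo, hi = fit.group_m_ratio_ci95
            hits += lo <= truth <= hi
        assert hits >= n_rep - 1
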