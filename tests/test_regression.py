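"""Latent regression: calibration, heteroscedastic fits, selection, tau,
age recoding and profile contrasts."""

import warnings

import numpy as np
import pytest

from latentpcm.design import indicator
from latentpcm.pcm import ItemBank, estimate_pce
from latentpcm.regression import (backward_select, calibrate_items,
                                  explained_variance_tau, fit_mixed_pcm,
                                  profile_deviation, recode_age_quantitative)
from latentpcm.sf36 import (published_age_recoding, published_fit,
                            published_tau_inputs, reference_profile)
from latentpcm.simulate import (FactorSpec, SimulationConfig, default_items,
                                simulate_dataset)


class TestCalibration:
    def test_variance_recovery(self, items_bank):
        items, thr, _ = items_bank
        cfg = SimulationConfig(n=5000, items=items, thresholds=thr,
                               sigma2_star=1.5, seed=31)
        resp, _, _ = simulate_dataset(cfg)
        bank, s2, info = calibrate_items(resp, items)
        # sampling SE of a variance estimate through the PCM is a few percent
        assert s2 == pytest.approx(1.5, abs=0.12)
        assert info["k"] == 16                       # 15 thresholds + variance

    def test_agrees_with_pce(self, items_bank):
        """Marginal ML and pairwise conditional estimation agree on large
        samples (both consistent for the same thresholds up to a shift)."""
        items, thr, _ = items_bank
        cfg = SimulationConfig(n=5000, items=items, thresholds=thr, seed=32)
        resp, _, _ = simulate_dataset(cfg)
        bank_mml, _, _ = calibrate_items(resp, items)
        bank_pce = estimate_pce(resp, items)
        a = np.concatenate([bank_mml[s.item_id] for s in items])
        b = np.concatenate([bank_pce[s.item_id] for s in items])
        a = a - a.mean()
        b = b - b.mean()                      # common shift is not identified
        assert np.abs(a - b).max() < 0.1

    def test_single_item_rejected(self):
        from latentpcm.questionnaire import ItemSpec, ResponseMatrix
        vals = np.array([[0.0], [1.0], [1.0], [0.0]])
        m = ResponseMatrix(vals, np.arange(4), ["A"])
        with pytest.raises(ValueError, match="at least 2"):
            calibrate_items(m, [ItemSpec("A", 2)])


@pytest.fixture(scope="module")
def hetero_fit():
    items, thr = default_items()
    bank = ItemBank([s.item_id for s in items],
                    [thr[s.item_id] for s in items])
    eff = indicator("g", "B", label="B")
    cfg = SimulationConfig(
        n=5000, items=items, thresholds=thr,
        factors=[FactorSpec("g", ("A", "B"), (0.5, 0.5))],
        mu_star=0.3, sigma2_star=1.2,
        beta=[(eff, -0.5)], gamma=[(eff, -0.4)], seed=33)
    resp, cov, _ = simulate_dataset(cfg)
    return fit_mixed_pcm(resp, bank, cov, [eff], [eff])


class TestMixedPCM:
    def test_mean_coefficient_recovery(self, hetero_fit):
        fit = hetero_fit
        assert abs(fit.beta[0] - (-0.5)) < 3 * fit.se[1]
        assert abs(fit.mu_star - 0.3) < 3 * fit.se[0]

    def test_variance_coefficient_recovery(self, hetero_fit):
        fit = hetero_fit
        assert abs(fit.gamma[0] - (-0.4)) < 3 * fit.se[3]
        assert abs(fit.sigma2_star - 1.2) < 3 * fit.se[2]

    def test_aic_identity(self, hetero_fit):
        fit = hetero_fit
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, rel=1e-12)
        assert fit.k == 4

    def test_empty_designs_reduce_to_calibration(self, items_bank):
        items, thr, _ = items_bank
        cfg = SimulationConfig(n=3000, items=items, thresholds=thr, seed=34)
        resp, cov, _ = simulate_dataset(cfg)
        bank, s2, _ = calibrate_items(resp, items)
        fit = fit_mixed_pcm(resp, bank, cov, [], [], compute_se=False)
        assert fit.mu_star == pytest.approx(0.0, abs=0.05)
        assert fit.sigma2_star == pytest.approx(s2, abs=0.05)

    def test_quadrature_refinement_stability(self, items_bank):
        items, thr, bank = items_bank
        eff = indicator("g", "B", label="B")
        cfg = SimulationConfig(
            n=800, items=items, thresholds=thr,
            factors=[FactorSpec("g", ("A", "B"), (0.5, 0.5))],
            beta=[(eff, -0.5)], seed=35)
        resp, cov, _ = simulate_dataset(cfg)
        f21 = fit_mixed_pcm(resp, bank, cov, [eff], [], n_nodes=21,
                            compute_se=False)
        f42 = fit_mixed_pcm(resp, bank, cov, [eff], [], n_nodes=42,
                            compute_se=False)
        assert abs(f21.loglik - f42.loglik) < 1e-4

    def test_nesting_never_decreases_loglik(self, items_bank):
        items, thr, bank = items_bank
        eff = indicator("g", "B", label="B")
        cfg = SimulationConfig(
            n=800, items=items, thresholds=thr,
            factors=[FactorSpec("g", ("A", "B"), (0.5, 0.5))], seed=36)
        resp, cov, _ = simulate_dataset(cfg)
        f0 = fit_mixed_pcm(resp, bank, cov, [], [], compute_se=False)
        f1 = fit_mixed_pcm(resp, bank, cov, [eff], [], compute_se=False)
        assert f1.loglik >= f0.loglik - 1e-6

    def test_rank_deficient_design_rejected(self, items_bank):
        items, thr, bank = items_bank
        cfg = SimulationConfig(
            n=200, items=items, thresholds=thr,
            factors=[FactorSpec("g", ("A", "B"), (0.5, 0.5))], seed=37)
        resp, cov, _ = simulate_dataset(cfg)
        both = [indicator("g", "A"), indicator("g", "B")]   # sums to intercept
        with pytest.raises(ValueError, match="rank deficient"):
            fit_mixed_pcm(resp, bank, cov, both, [])


@pytest.fixture(scope="module")
def selection():
    items, thr = default_items()
    bank = ItemBank([s.item_id for s in items],
                    [thr[s.item_id] for s in items])
    real = indicator("g", "B", label="real")
    noise = indicator("h", "Y", label="noise")
    cfg = SimulationConfig(
        n=3000, items=items, thresholds=thr,
        factors=[FactorSpec("g", ("A", "B"), (0.5, 0.5)),
                 FactorSpec("h", ("X", "Y"), (0.5, 0.5))],
        beta=[(real, 0.5)], seed=38)
    resp, cov, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, log = backward_select(resp, bank, cov, [real, noise], [noise])
    return fit, log


class TestBackwardSelection:
    def test_noise_removed_true_effect_kept(self, selection):
        fit, log = selection
        kept = [e.label for e in fit.mean_effects]
        assert kept == ["real"]
        removed = [r["term"] for r in log if r["stage"] == "mean"]
        assert "noise" in removed

    def test_noise_variance_term_removed(self, selection):
        fit, _ = selection
        assert fit.var_effects == []

    def test_removal_log_records_aic(self, selection):
        _, log = selection
        for rec in log:
            assert rec["aic_after"] <= rec["aic_before"]

    def test_no_candidates_returns_intercept_fit(self, items_bank):
        items, thr, bank = items_bank
        cfg = SimulationConfig(n=400, items=items, thresholds=thr, seed=39)
        resp, cov, _ = simulate_dataset(cfg)
        fit, log = backward_select(resp, bank, cov, [], [])
        assert fit.mean_effects == [] and fit.var_effects == [] and log == []


class TestTau:
    @pytest.mark.parametrize("dim,expected", [("GH", 13), ("PF", 27),
                                              ("MH", 5)])
    def test_survey_explained_variance_rates(self, dim, expected):
        n, k0, s0, k, s = published_tau_inputs(dim)
        tau = explained_variance_tau(s0, k0, s, k, n)
        assert round(100 * tau) == expected

    def test_identical_models_zero(self):
        assert explained_variance_tau(1.3, 10, 1.3, 10, 1000) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            explained_variance_tau(-1.0, 5, 1.0, 5, 100)
        with pytest.raises(ValueError):
            explained_variance_tau(1.0, 99, 1.0, 5, 100)


class TestAgeRecoding:
    def test_ratio_extraction(self):
        coefs = [0.0, -0.6, -1.2, -2.4, -3.6, -4.8, -6.0]
        rec = recode_age_quantitative(coefs)
        assert rec.scores == (0., 1., 2., 4., 6., 8., 10.)

    def test_linear_pattern(self):
        rec = recode_age_quantitative([0.0, -1.0, -2.0, -3.0])
        assert rec.scores == (0., 1., 2., 3.)

    def test_all_zero_refused(self):
        with pytest.raises(ValueError, match="refused"):
            recode_age_quantitative([0.0, 0.0, 0.0])

    def test_non_monotone_warns_and_projects(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            rec = recode_age_quantitative([0.0, -1.0, -0.5, -2.0],
                                          isotonic=True)
        assert all(b >= a for a, b in zip(rec.scores, rec.scores[1:]))

    def test_survey_recodings_reproduce_published_deviations(self):
        """The published age-band deviations divided by the trend coefficient
        give the published integer scores."""
        gh_men_1995 = [0.0, -0.07, -0.42, -0.59, -0.84, -1.12, -1.40]
        rec = recode_age_quantitative(np.array(gh_men_1995))
        # unit is -0.035 (the 25-34 deviation / 2 steps rounds to the same)
        assert rec.scores == published_age_recoding["GH"].scores


class TestProfileDeviation:
    def test_reference_is_zero(self):
        fit = published_fit("PF")
        ref = reference_profile()
        assert profile_deviation(fit, ref, ref) == 0.0

    def test_pf_men_oldest_band(self):
        fit = published_fit("PF")
        ref = reference_profile()
        old = reference_profile(age_band="75-84", ager=10.0)
        assert round(profile_deviation(fit, old, ref), 2) == -5.96

    def test_pf_women_oldest_band(self):
        fit = published_fit("PF")
        ref = reference_profile(gender="Women")
        old = reference_profile(gender="Women", age_band="75-84", ager=10.0)
        assert round(profile_deviation(fit, old, ref), 2) == -5.29

    def test_unknown_covariate_rejected(self):
        fit = published_fit("PF")
        with pytest.raises(ValueError, match="profile lacks"):
            profile_deviation(fit, {"gender": "Men"}, {"gender": "Men"})

    def test_variance_component(self):
        fit = published_fit("GH")
        ref = reference_profile()
        old = reference_profile(ager=40.0)
        dev = profile_deviation(fit, old, ref, component="variance")
        assert round(dev, 2) == -0.27       # 1995 age trend of the variance
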