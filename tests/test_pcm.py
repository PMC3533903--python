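"""PCM probabilities, pairwise conditional estimation, EAP estimates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentpcm.pcm import (ItemBank, collapse_unobserved, eap_estimate,
                           estimate_pce, expected_score,
                           pairwise_conditional_loglik, pcm_category_probs)
from latentpcm.questionnaire import ItemSpec, ResponseMatrix
from latentpcm.simulate import (SimulationConfig, apply_missingness,
                                simulate_dataset)


def brute_pcm_probs(theta, delta):
    """Independent oracle: direct evaluation of the unnormalized terms."""
    terms = []
    for y in range(len(delta) + 1):
        terms.append(math.exp(y * theta - sum(delta[:y])))
    z = sum(terms)
    return [t / z for t in terms]


class TestCategoryProbs:
    def test_dichotomous_logistic_symmetry(self):
        np.testing.assert_allclose(pcm_category_probs(0.0, [0.0]), [0.5, 0.5])

    def test_three_category_hand_evaluation(self):
        got = pcm_category_probs(0.0, [-1.0, 1.0])
        want = brute_pcm_probs(0.0, [-1.0, 1.0])
        np.testing.assert_allclose(got, want, rtol=1e-12)

    @given(st.floats(-40, 40),
           st.lists(st.floats(-5, 5), min_size=1, max_size=5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalization_and_oracle(self, theta, delta):
        p = pcm_category_probs(theta, delta)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()
        if abs(theta) < 20:      # brute oracle overflows beyond
            np.testing.assert_allclose(p, brute_pcm_probs(theta, delta),
                                       rtol=1e-9, atol=1e-12)

    def test_dichotomous_equals_rasch_closed_form(self):
        for theta in np.linspace(-6, 6, 25):
            for d in (-2.0, 0.0, 1.5):
                p = pcm_category_probs(theta, [d])
                assert p[1] == pytest.approx(1 / (1 + math.exp(d - theta)),
                                             rel=1e-12)


class TestExpectedScore:
    def test_limits(self):
        delta = [-1.0, 0.0, 1.0]
        assert expected_score(-40.0, delta) == pytest.approx(0.0, abs=1e-10)
        assert expected_score(40.0, delta) == pytest.approx(3.0, abs=1e-10)
        assert expected_score(0.0, [0.0]) == pytest.approx(0.5)

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(-8, 8, 100)
        vals = [expected_score(t, [-1.0, 0.5, 2.0]) for t in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestPCE:
    def test_symmetric_dichotomous_items_mirror(self, dichotomous_specs):
        # margins of A and B are mirror images, so the sum-zero constraint
        # forces opposite thresholds
        vals = np.array([[1, 0]] * 30 + [[0, 1]] * 10 +
                        [[0, 0]] * 20 + [[1, 1]] * 20, dtype=float)
        m = ResponseMatrix(vals, np.arange(len(vals)), ["A", "B"])
        bank = estimate_pce(m, dichotomous_specs)
        assert bank["A"][0] == pytest.approx(-bank["B"][0], abs=1e-6)

    def test_toy_conditional_likelihood_matches_enumeration(self):
        """The fitted objective equals brute-force conditioning of the PCM
        joint distribution on the pair total (theta cancels)."""
        vals = np.array([[0, 2], [1, 1], [2, 0], [2, 2]], dtype=float)
        m = ResponseMatrix(vals, np.arange(4), ["A", "B"])
        bank = ItemBank(["A", "B"], [np.array([-0.5, 0.3]),
                                     np.array([0.2, -0.1])])
        theta = 0.7                        # arbitrary: result must not depend
        ll = 0.0
        for a, b in vals.astype(int):
            pa = brute_pcm_probs(theta, list(bank["A"]))
            pb = brute_pcm_probs(theta, list(bank["B"]))
            t = a + b
            num = pa[a] * pb[b]
            den = sum(pa[c] * pb[t - c] for c in range(3)
                      if 0 <= t - c <= 2)
            ll += math.log(num / den)
        assert pairwise_conditional_loglik(m, bank) == pytest.approx(ll,
                                                                     rel=1e-10)
        ll2 = 0.0                          # theta-free: same at another theta
        for a, b in vals.astype(int):
            pa = brute_pcm_probs(-1.3, list(bank["A"]))
            pb = brute_pcm_probs(-1.3, list(bank["B"]))
            t = a + b
            den = sum(pa[c] * pb[t - c] for c in range(3) if 0 <= t - c <= 2)
            ll2 += math.log(pa[a] * pb[b] / den)
        assert ll2 == pytest.approx(ll, rel=1e-10)

    def test_recovery_on_simulated_data(self, items_bank):
        items, thr, _ = items_bank
        cfg = SimulationConfig(n=2000, items=items, thresholds=thr, seed=17)
        resp, _, _ = simulate_dataset(cfg)
        bank = estimate_pce(resp, items)
        err = np.concatenate([bank[s.item_id] - thr[s.item_id] for s in items])
        assert np.sqrt(np.mean(err ** 2)) < 0.15

    def test_sum_zero_constraint(self, items_bank):
        items, thr, _ = items_bank
        cfg = SimulationConfig(n=500, items=items, thresholds=thr, seed=21)
        resp, _, _ = simulate_dataset(cfg)
        bank = estimate_pce(resp, items)
        total = sum(bank[s.item_id].sum() for s in items)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_consistency_under_mcar(self, items_bank):
        """Specific objectivity: 20% MCAR missingness leaves the estimates
        within sampling tolerance."""
        items, thr, _ = items_bank
        cfg = SimulationConfig(n=4000, items=items, thresholds=thr, seed=23)
        resp, _, theta = simulate_dataset(cfg)
        full = estimate_pce(resp, items)
        holey = apply_missingness(resp, theta, ("mcar", 0.2),
                                  np.random.default_rng(99))
        part = estimate_pce(holey, items)
        diffs = np.concatenate([full[s.item_id] - part[s.item_id]
                                for s in items])
        assert np.abs(diffs).max() < 0.25

    def test_unobserved_category_collapsed_with_warning(self):
        vals = np.array([[0, 0], [0, 1], [3, 1], [3, 0], [0, 1], [3, 1]],
                        dtype=float)
        m = ResponseMatrix(vals, np.arange(6), ["A", "B"])
        specs = [ItemSpec("A", 4), ItemSpec("B", 2)]
        with pytest.warns(UserWarning, match="collapsed"):
            out, new_m, mapping = collapse_unobserved(m, {"A": 3, "B": 1})
        assert new_m["A"] == 1                    # 4 categories -> 2
        assert mapping["A"] == [0, -1, -1, 1]
        assert set(out.column("A")) == {0.0, 1.0}


class TestEAP:
    def test_all_missing_person_is_nan(self, items_bank):
        items, thr, bank = items_bank
        vals = np.array([[np.nan] * 5, [1, 1, 1, 1, 1]], dtype=float)
        m = ResponseMatrix(vals, np.arange(2), bank.item_ids)
        est = eap_estimate(m, bank)
        assert np.isnan(est[0]) and np.isfinite(est[1])

    def test_monotone_in_total_score(self, items_bank):
        items, thr, bank = items_bank
        vals = np.array([[0] * 5, [1] * 5, [3] * 5], dtype=float)
        m = ResponseMatrix(vals, np.arange(3), bank.item_ids)
        est = eap_estimate(m, bank)
        assert est[0] < est[1] < est[2]

    def test_quadrature_refinement_agreement(self, items_bank):
        items, thr, bank = items_bank
        vals = np.array([[0, 1, 2, 3, 1], [2, 2, 2, np.nan, 0]], dtype=float)
        m = ResponseMatrix(vals, np.arange(2), bank.item_ids)
        a = eap_estimate(m, bank, n_nodes=61)
        b = eap_estimate(m, bank, n_nodes=121)
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestItemBankIO:
    def test_csv_roundtrip(self, items_bank, tmp_path):
        _, _, bank = items_bank
        path = tmp_path / "bank.csv"
        bank.to_csv(path)
        back = ItemBank.from_csv(path)
        assert back.item_ids == bank.item_ids
        for iid in bank.item_ids:
            np.testing.assert_allclose(back[iid], bank[iid], rtol=1e-11)

    def test_locations_are_threshold_means(self, items_bank):
        _, thr, bank = items_bank
        locs = bank.locations()
        for iid in bank.item_ids:
            assert locs[iid] == pytest.approx(np.mean(thr[iid]))
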