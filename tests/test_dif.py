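"""Two-stage DIF scan: stratum fits, weighted ANOVA, level collapsing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from latentpcm.dif import (DIFReport, LocationTable, collapse_levels,
                           fit_strata_locations, second_stage_region_year,
                           weighted_anova_dif)
from latentpcm.simulate import (FactorSpec, SimulationConfig, default_items,
                                simulate_dataset)
from latentpcm.design import indicator


def _survey_cfg(n, seed, n_age=3, n_region=3, **kw):
    items, thr = default_items()
    factors = [
        FactorSpec("gender", ("Men", "Women"), (0.5, 0.5)),
        FactorSpec("age_band", tuple(f"a{i}" for i in range(n_age)),
                   tuple([1.0 / n_age] * n_age)),
        FactorSpec("region", tuple(f"r{i}" for i in range(n_region)),
                   tuple([1.0 / n_region] * n_region)),
        FactorSpec("year", ("1995", "2003"), (0.4, 0.6)),
    ]
    return SimulationConfig(n=n, items=items, thresholds=thr, factors=factors,
                            seed=seed, **kw)


class TestStrataFits:
    def test_stratum_counts(self):
        cfg = _survey_cfg(5600, seed=1, n_age=7)
        resp, cov, _ = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loc = fit_strata_locations(resp, cov,
                                       ["gender", "age_band", "year"],
                                       cfg.items, min_stratum_size=10)
        assert len(loc.table) == 2 * 7 * 2          # 28 strata
        loc2 = fit_strata_locations(resp, cov, ["region", "year"], cfg.items,
                                    min_stratum_size=10)
        assert len(loc2.table) == 3 * 2
        loc3 = fit_strata_locations(resp, cov, ["gender"], cfg.items)
        assert len(loc3.table) == 2

    def test_small_strata_dropped_with_warning(self):
        cfg = _survey_cfg(300, seed=2, n_age=7)
        resp, cov, _ = simulate_dataset(cfg)
        with pytest.warns(UserWarning, match="dropped"):
            loc = fit_strata_locations(resp, cov, ["gender", "age_band", "year"],
                                       cfg.items, min_stratum_size=20)
        assert len(loc.table) < 28
        assert (loc.sizes >= 20).all()


class TestWeightedAnova:
    def _table(self, locs_by_stratum, sizes):
        idx = pd.MultiIndex.from_tuples(list(locs_by_stratum),
                                        names=["gender", "year"])
        df = pd.DataFrame({"I1": [v for v in locs_by_stratum.values()]},
                          index=idx)
        return LocationTable(df, pd.Series(sizes, index=idx),
                             ["gender", "year"])

    def test_constant_locations_no_flags(self):
        tab = self._table({("M", "1995"): 0.2, ("M", "2003"): 0.2,
                           ("F", "1995"): 0.2, ("F", "2003"): 0.2},
                          [100, 100, 100, 100])
        rep = weighted_anova_dif(tab)
        assert not rep.table["flag"].any()
        assert (rep.table["diff"] == 0).all()

    def test_small_difference_not_flagged_despite_significance(self):
        """The flag is a conjunction: a 0.05 shift stays unflagged even when
        huge strata make it highly significant."""
        rng = np.random.default_rng(3)
        rows = {}
        for g in ("M", "F"):
            for a in ("y", "m", "o"):
                for y in ("1995", "2003"):
                    shift = 0.05 if g == "F" else 0.0
                    rows[(g, a, y)] = shift + rng.normal(0, 0.005)
        idx = pd.MultiIndex.from_tuples(list(rows),
                                        names=["gender", "age", "year"])
        tab = LocationTable(pd.DataFrame({"I1": list(rows.values())}, index=idx),
                            pd.Series(10_000, index=idx),
                            ["gender", "age", "year"])
        rep = weighted_anova_dif(tab)
        row = rep.table[(rep.table["item"] == "I1")
                        & (rep.table["factor"] == "gender")].iloc[0]
        assert row["p"] < 0.05 and row["diff"] <= 0.1 and not row["flag"]

    def test_injected_gender_shift_flagged(self):
        cfg = _survey_cfg(8000, seed=4,
                          beta=[(indicator("gender", "Women"), -0.5)],
                          dif_offsets={("I2", "gender", "Women"): 0.5})
        resp, cov, _ = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loc = fit_strata_locations(resp, cov,
                                       ["gender", "age_band", "year"],
                                       cfg.items)
        rep = weighted_anova_dif(loc)
        row = rep.table[(rep.table["item"] == "I2")
                        & (rep.table["factor"] == "gender")].iloc[0]
        assert row["flag"] and row["diff"] > 0.3


class TestCollapseLevels:
    def test_greedy_two_clusters(self):
        means = pd.Series([0.0, 0.02, 0.5, 0.52], index=list("abcd"))
        assert collapse_levels(means) == [["a", "b"], ["c", "d"]]

    def test_all_close_single_group(self):
        means = pd.Series([0.0, 0.04, 0.08], index=list("abc"))
        assert collapse_levels(means) == [["a", "b", "c"]]

    def test_spaced_means_singletons(self):
        means = pd.Series([0.0, 0.2, 0.4], index=list("abc"))
        assert collapse_levels(means) == [["a"], ["b"], ["c"]]

    def test_unordered_sorts_by_mean(self):
        means = pd.Series([0.5, 0.0, 0.52], index=list("abc"))
        assert collapse_levels(means, ordered=False) == [["b"], ["a", "c"]]


class TestSecondStage:
    def test_year_shift_flagged(self):
        cfg = _survey_cfg(9000, seed=5,
                          dif_offsets={("I4", "year", "2003"): 0.4})
        resp, cov, _ = simulate_dataset(cfg)
        stage1 = DIFReport(pd.DataFrame(
            columns=["item", "factor", "diff", "p", "flag", "grouping"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep2 = second_stage_region_year(resp, cov, stage1, cfg.items)
        row = rep2.table[(rep2.table["item"] == "I4")
                         & (rep2.table["factor"] == "year")].iloc[0]
        assert row["flag"]

    def test_impact_without_dif_not_flagged(self):
        """Region effects on the latent MEAN must not trigger region DIF:
        locations are trait-free."""
        cfg = _survey_cfg(9000, seed=6,
                          beta=[(indicator("region", "r1"), -0.8),
                                (indicator("region", "r2"), 0.6)])
        resp, cov, _ = simulate_dataset(cfg)
        stage1 = DIFReport(pd.DataFrame(
            columns=["item", "factor", "diff", "p", "flag", "grouping"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep2 = second_stage_region_year(resp, cov, stage1, cfg.items)
        region = rep2.table[rep2.table["factor"] == "region"]
        assert not region["flag"].any()

    def test_stage1_splits_fold_back_to_one_location(self):
        cfg = _survey_cfg(6000, seed=7)
        resp, cov, _ = simulate_dataset(cfg)
        stage1 = DIFReport(pd.DataFrame([{
            "item": "I1", "factor": "gender", "diff": 0.3, "p": 0.001,
            "flag": True, "grouping": [["Men"], ["Women"]]}]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep2 = second_stage_region_year(resp, cov, stage1, cfg.items)
        assert set(rep2.table["item"]) == {s.item_id for s in cfg.items}
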