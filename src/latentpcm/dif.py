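"""Two-stage differential item functioning (DIF) scan on item locations.

Stage 1 fits a Partial Credit Model separately inside every stratum of the
demographic factors (e.g. gender x age band x survey year), extracts each
item's location (mean threshold) under the common sum-zero constraint, and
runs a main-effects ANOVA of location on the factors, weighted by stratum
size.  An item shows large DIF on a factor when the factor is significant at
5% AND the spread of its weighted level-mean locations exceeds 0.1 logits.
Flagged factors get their levels collapsed greedily into groups whose location
spread stays within the 0.1 threshold.

Stage 2 repeats the scan for region x survey year after expanding stage-1 DIF
items into pseudo-items, so that first-stage DIF cannot masquerade as regional
or temporal DIF; a split item's location in a stratum is the observation-count
weighted average of its pseudo-item locations.

Because item locations are trait-free (conditional estimation), true group
differences in the latent trait ("impact") do not produce DIF flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pcm import estimate_pce
from .questionnaire import DIFSpec, ItemSpec, ResponseMatrix, expand_pseudo_items

__all__ = [
    "LocationTable",
    "DIFReport",
    "fit_strata_locations",
    "weighted_anova_dif",
    "collapse_levels",
    "second_stage_region_year",
]


@dataclass
class LocationTable:
    """Estimated item locations per stratum (one PCE fit per row)."""

    table: pd.DataFrame          # index: MultiIndex of factor levels; cols: items
    sizes: pd.Series             # persons per stratum
    factors: list[str]


@dataclass
class DIFReport:
    """Per item x factor: p-value, max location difference, flag, grouping."""

    table: pd.DataFrame          # columns: item, factor, diff, p, flag, grouping
    level_means: dict = field(default_factory=dict)   # (item, factor) -> Series

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flag"]]

    def to_dif_spec(self) -> DIFSpec:
        splits: dict[str, list] = {}
        for _, row in self.flagged().iterrows():
            if row["grouping"] is not None and len(row["grouping"]) > 1:
                splits.setdefault(row["item"], []).append(
                    (row["factor"], row["grouping"]))
        return DIFSpec(splits)


def fit_strata_locations(
    matrix: ResponseMatrix,
    covariates: pd.DataFrame,
    factors: list[str],
    items: list[ItemSpec] | None = None,
    min_stratum_size: int = 30,
) -> LocationTable:
    """One PCE fit per factor-level combination; locations per item.

    Strata below ``min_stratum_size`` persons are dropped with a warning; a
    failed or degenerate stratum fit leaves NaN cells.
    """
    if len(covariates) != matrix.n_persons:
        raise ValueError("covariate table not aligned with response matrix")
    keys = covariates[factors].astype(str)
    rows, sizes, index = [], [], []
    for combo, idx in keys.groupby(factors, sort=True).groups.items():
        combo = combo if isinstance(combo, tuple) else (combo,)
        pos = keys.index.get_indexer(idx)
        if len(pos) < min_stratum_size:
            warnings.warn(f"stratum {combo}: only {len(pos)} persons; dropped",
                          stacklevel=2)
            continue
        sub = ResponseMatrix(matrix.values[pos], matrix.person_ids[pos],
                             list(matrix.item_ids)).drop_empty_persons()
        loc = pd.Series(np.nan, index=matrix.item_ids)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bank = estimate_pce(sub, items)
            loc.update(bank.locations())
        except ValueError as err:
            warnings.warn(f"stratum {combo}: PCE failed ({err}); cells missing",
                          stacklevel=2)
        rows.append(loc)
        sizes.append(sub.n_persons)
        index.append(combo)
    if not rows:
        raise ValueError("no stratum was large enough to fit")
    mi = pd.MultiIndex.from_tuples(index, names=factors)
    return LocationTable(pd.DataFrame(rows, index=mi),
                         pd.Series(sizes, index=mi, name="n"), list(factors))


def _weighted_level_means(df: pd.DataFrame, factor: str) -> pd.Series:
    g = df.groupby(factor, sort=False)
    return g.apply(lambda d: np.average(d["loc"], weights=d["w"]),
                   include_groups=False)


def weighted_anova_dif(
    loc_table: LocationTable,
    factors: list[str] | None = None,
    alpha: float = 0.05,
    diff_threshold: float = 0.1,
    ordered_factors: dict[str, list[str]] | None = None,
) -> DIFReport:
    """Weighted main-effects ANOVA of item location on the strata factors.

    Weights are stratum sizes.  Per item and factor the report carries the
    F-test p-value, the maximal pairwise difference of weighted level-mean
    locations, the large-DIF flag (p < alpha AND diff > threshold) and, when
    flagged, the collapsed level grouping (a collapse to a single group
    rescinds the flag).  ``ordered_factors`` gives the level order of ordinal
    factors (e.g. age bands) for adjacent-level collapsing.
    """
    factors = factors or loc_table.factors
    ordered_factors = ordered_factors or {}
    recs, level_means = [], {}
    for item in loc_table.table.columns:
        df = loc_table.table[[item]].rename(columns={item: "loc"}).copy()
        df["w"] = loc_table.sizes
        df = df.reset_index().dropna(subset=["loc"])
        dummies, spans = [], {}
        for f in factors:
            d = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True,
                               dtype=float)
            spans[f] = list(d.columns)
            dummies.append(d)
        X = sm.add_constant(pd.concat(dummies, axis=1))
        res = None
        if len(df) > X.shape[1]:
            try:
                res = sm.WLS(df["loc"], X, weights=df["w"]).fit()
            except Exception:
                res = None
        for f in factors:
            means = _weighted_level_means(df, f)
            if f in ordered_factors:
                means = means.reindex([lv for lv in ordered_factors[f]
                                       if lv in means.index])
            level_means[(item, f)] = means
            diff = float(means.max() - means.min()) if len(means) > 1 else 0.0
            p = np.nan
            if res is not None and spans[f]:
                cols = [c for c in spans[f] if c in X.columns]
                R = np.zeros((len(cols), X.shape[1]))
                for i, c in enumerate(cols):
                    R[i, list(X.columns).index(c)] = 1.0
                try:
                    p = float(res.f_test(R).pvalue)
                except Exception:
                    p = np.nan
            flag = bool(np.isfinite(p) and p < alpha and diff > diff_threshold)
            grouping = None
            if flag:
                grouping = collapse_levels(means, ordered=f in ordered_factors,
                                           spread=diff_threshold)
                if len(grouping) < 2:
                    flag = False
            recs.append({"item": item, "factor": f, "diff": diff, "p": p,
                         "flag": flag, "grouping": grouping})
    return DIFReport(pd.DataFrame(recs), level_means)


def collapse_levels(level_means: pd.Series, ordered: bool = True,
                    spread: float = 0.1) -> list[list[str]]:
    """Greedy merge of (adjacent) levels while the group's location spread
    stays within ``spread``.

    ``level_means`` must be in level order for ordered factors; unordered
    factors are sorted by mean location first.
    """
    means = level_means if ordered else level_means.sort_values()
    groups: list[list[str]] = []
    lo = hi = None
    for lv, m in means.items():
        if lo is None or max(hi, m) - min(lo, m) > spread:
            groups.append([str(lv)])
            lo = hi = m
        else:
            groups[-1].append(str(lv))
            lo, hi = min(lo, m), max(hi, m)
    return groups


def second_stage_region_year(
    matrix: ResponseMatrix,
    covariates: pd.DataFrame,
    stage1: DIFReport,
    items: list[ItemSpec] | None = None,
    region_factor: str = "region",
    year_factor: str = "year",
    alpha: float = 0.05,
    diff_threshold: float = 0.1,
    min_stratum_size: int = 30,
) -> DIFReport:
    """Region x year DIF scan adjusted for stage-1 gender/age DIF.

    Stage-1 DIF items are expanded into pseudo-items before the per-stratum
    fits; a split item's stratum location is then the observation-count
    weighted average of its pseudo-item locations, giving one location per
    original item for the weighted ANOVA on region and year.
    """
    dif_spec = stage1.to_dif_spec()
    expanded, specs = expand_pseudo_items(matrix, covariates, dif_spec, items)
    loc = fit_strata_locations(expanded, covariates,
                               [region_factor, year_factor], specs,
                               min_stratum_size=min_stratum_size)
    # fold pseudo-item locations back onto their source items
    source = {s.item_id: s.item_id.split("@", 1)[0] for s in specs}
    counts = pd.DataFrame(index=loc.table.index, columns=loc.table.columns,
                          dtype=float)
    keys = covariates[[region_factor, year_factor]].astype(str)
    obs = pd.DataFrame(expanded.observed(), columns=expanded.item_ids)
    obs[[region_factor, year_factor]] = keys.to_numpy()
    cnt = obs.groupby([region_factor, year_factor], sort=True).sum()
    counts.loc[cnt.index, cnt.columns] = cnt.astype(float)
    folded = {}
    for orig in dict.fromkeys(source.values()):
        cols = [c for c in loc.table.columns if source[c] == orig]
        w = counts[cols].to_numpy()
        v = loc.table[cols].to_numpy()
        ok = np.isfinite(v) & (w > 0)
        wsum = np.where(ok, w, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            folded[orig] = np.where(
                wsum > 0,
                np.where(ok, v * w, 0.0).sum(axis=1) / wsum, np.nan)
    folded_table = LocationTable(pd.DataFrame(folded, index=loc.table.index),
                                 loc.sizes, loc.factors)
    return weighted_anova_dif(folded_table, [region_factor, year_factor],
                              alpha=alpha, diff_threshold=diff_threshold)
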