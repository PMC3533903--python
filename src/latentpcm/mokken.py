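"""Nonparametric IRT assumption checks: Loevinger scalability and monotonicity.

Under the Monotone Homogeneity Model (unidimensionality, local independence,
monotone step response functions), inter-item covariances are non-negative and
bounded by the covariance of the maximally concordant joint distribution with
the same margins.  Loevinger's coefficients take the ratio of the two:

    H_jk = Cov(Y_j, Y_k) / Cov_max(Y_j, Y_k)

with ``H_j`` and ``H`` aggregating numerators and denominators over the pairs
involving item j / all pairs.  The conventional gates are H > 0.3, every
H_j > 0.3 and every H_jk > 0.

Monotonicity is checked per item by estimating each step response function
P(Y_j >= l) across rest-score groups and scoring decreases with the composite
criterion ``Crit`` of the MSP tradition (weighted sum of the H_j shortfall
below 0.30, violation counts, magnitudes and z statistics); values below 40
are conventionally acceptable, and the criterion is negative when there is no
violation and H_j exceeds 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .questionnaire import ResponseMatrix

__all__ = [
    "ScalabilityReport",
    "MonotonicityResult",
    "loevinger_coefficients",
    "check_mhm_fit",
    "monotonicity_check",
    "monotonicity_all",
]


# ---------------------------------------------------------------------------
# Loevinger coefficients
# ---------------------------------------------------------------------------

def _pair_cov_terms(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(observed covariance, maximal covariance under the same margins).

    The comonotone coupling of two samples of equal size pairs sorted values
    elementwise, which maximizes E[XY] for fixed empirical margins.
    """
    n = x.size
    num = float(np.mean(x * y) - x.mean() * y.mean())
    den = float(np.mean(np.sort(x) * np.sort(y)) - x.mean() * y.mean())
    return num, den


@dataclass
class ScalabilityReport:
    H: float
    H_j: pd.Series
    H_jk: pd.DataFrame
    pair_num: pd.DataFrame
    pair_den: pd.DataFrame
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)
    monotonicity: pd.DataFrame | None = None


def loevinger_coefficients(matrix: ResponseMatrix) -> ScalabilityReport:
    """H, per-item H_j and per-pair H_jk on pairwise-complete cases.

    A zero-variance item makes its pairs undefined (reported, excluded from
    aggregation).  ``H = sum(numerators) / sum(denominators)`` exactly.
    """
    if matrix.n_items < 2:
        raise ValueError("scalability needs at least 2 items")
    ids = matrix.item_ids
    J = len(ids)
    num = np.full((J, J), np.nan)
    den = np.full((J, J), np.nan)
    undefined = []
    vals = matrix.values
    for j in range(J):
        for k in range(j + 1, J):
            both = ~np.isnan(vals[:, j]) & ~np.isnan(vals[:, k])
            if both.sum() < 2:
                undefined.append((ids[j], ids[k]))
                continue
            njk, djk = _pair_cov_terms(vals[both, j], vals[both, k])
            if djk <= 0:
                undefined.append((ids[j], ids[k]))
                continue
            num[j, k] = num[k, j] = njk
            den[j, k] = den[k, j] = djk
    with np.errstate(invalid="ignore"):
        hjk = num / den
    ok = ~np.isnan(den)
    den_total = np.nansum(np.triu(den, 1)[np.triu(ok, 1)])
    H = (float(np.nansum(np.triu(num, 1)[np.triu(ok, 1)]) / den_total)
         if den_total > 0 else np.nan)
    hj = pd.Series({ids[j]: np.nansum(num[j]) / np.nansum(den[j])
                    if ok[j].any() else np.nan for j in range(J)})
    return ScalabilityReport(
        H=H,
        H_j=hj,
        H_jk=pd.DataFrame(hjk, index=ids, columns=ids),
        pair_num=pd.DataFrame(num, index=ids, columns=ids),
        pair_den=pd.DataFrame(den, index=ids, columns=ids),
        undefined_pairs=undefined,
    )


def check_mhm_fit(report: ScalabilityReport, h_min: float = 0.3,
                  hj_min: float = 0.3, hjk_min: float = 0.0,
                  crit_max: float = 40.0) -> tuple[bool, list[str]]:
    """Gate the Monotone Homogeneity Model fit; returns (pass, violations)."""
    reasons = []
    if not report.H > h_min:
        reasons.append(f"H <= {h_min} (H = {report.H:.3f})")
    bad_j = report.H_j[report.H_j <= hj_min]
    for iid, v in bad_j.items():
        reasons.append(f"H_j <= {hj_min} for {iid} (H_j = {v:.3f})")
    tri = report.H_jk.where(np.triu(np.ones(report.H_jk.shape, bool), 1))
    worst = tri.stack().min() if tri.stack().size else np.nan
    if np.isfinite(worst) and not worst > hjk_min:
        reasons.append(f"min H_jk <= {hjk_min} (min = {worst:.3f})")
    if report.undefined_pairs:
        reasons.append(f"undefined pairs: {report.undefined_pairs}")
    if report.monotonicity is not None:
        bad = report.monotonicity[report.monotonicity["crit"] >= crit_max]
        for iid in bad["item"]:
            reasons.append(f"Crit >= {crit_max} for {iid}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# monotonicity
# ---------------------------------------------------------------------------

@dataclass
class MonotonicityResult:
    item: str
    n_groups: int
    n_active: int          # step x group-pair comparisons examined
    n_violations: int
    max_violation: float
    sum_violations: float
    max_z: float
    sum_z: float
    crit: float
    group_sizes: list[int] = field(default_factory=list)
    step_props: np.ndarray | None = None   # (groups, steps) P(Y >= l)


def _rest_score_groups(rest: np.ndarray, min_group_size: int) -> np.ndarray:
    """Group labels from rest scores, merging adjacent scores upward until
    every group reaches ``min_group_size`` (a trailing small group merges
    backward)."""
    order = np.unique(rest)
    labels = np.full(rest.size, -1, dtype=int)
    g, count = 0, 0
    for s in order:
        mask = rest == s
        labels[mask] = g
        count += int(mask.sum())
        if count >= min_group_size:
            g, count = g + 1, 0
    if count and g > 0:          # leftover too small: merge into previous group
        labels[labels == g] = g - 1
    return labels


def monotonicity_check(
    matrix: ResponseMatrix,
    item_id: str,
    min_group_size: int | None = None,
    minvi: float = 0.03,
    hj: float | None = None,
) -> MonotonicityResult:
    """Monotonicity diagnostics for one item.

    Complete cases over the item set; the rest score is the total over the
    other items.  For every item step ``l`` and every ordered pair of
    rest-score groups, a decrease of the estimated P(Y >= l) larger than
    ``minvi`` counts as a violation, with a two-proportion z statistic.  The
    composite is::

        Crit = 50(0.30 - H_j) + sqrt(#vi) + 100 #vi/#ac + 100 maxvi
               + 10 sqrt(sum vi) + 1000 sum(vi)/#ac
               + 5 max(z) + 10 sqrt(sum z) + 100 sum(z)/#ac

    which is 0 when there is no violation and H_j = 0.30 (negative beyond).
    """
    j = matrix.item_ids.index(item_id)
    complete = matrix.observed().all(axis=1)
    vals = matrix.values[complete]
    if vals.shape[0] == 0:
        raise ValueError("no complete cases for monotonicity check")
    y = vals[:, j].astype(int)
    rest = np.delete(vals, j, axis=1).sum(axis=1).astype(int)
    n = y.size
    if min_group_size is None:
        min_group_size = min(max(n // 10, 1), 500)
    labels = _rest_score_groups(rest, min_group_size)
    n_groups = labels.max() + 1
    if hj is None:
        hj = float(loevinger_coefficients(matrix).H_j[item_id])

    m = int(np.nanmax(matrix.values[:, j]))
    if n_groups < 2:
        return MonotonicityResult(item_id, n_groups, 0, 0, 0.0, 0.0, 0.0, 0.0,
                                  crit=50.0 * (0.30 - hj),
                                  group_sizes=[n] if n_groups else [])

    sizes = np.array([(labels == g).sum() for g in range(n_groups)])
    props = np.empty((n_groups, m))
    for g in range(n_groups):
        yy = y[labels == g]
        props[g] = [(yy >= l).mean() for l in range(1, m + 1)]

    vi, zs = [], []
    n_active = 0
    for l in range(m):
        for g1 in range(n_groups):
            for g2 in range(g1 + 1, n_groups):
                n_active += 1
                drop = props[g1, l] - props[g2, l]
                if drop > minvi:
                    p1, p2 = props[g1, l], props[g2, l]
                    n1, n2 = sizes[g1], sizes[g2]
                    pool = (p1 * n1 + p2 * n2) / (n1 + n2)
                    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
                    vi.append(drop)
                    zs.append(drop / se if se > 0 else 0.0)
    vi = np.array(vi)
    zs = np.array(zs)
    crit = 50.0 * (0.30 - hj)
    if vi.size:
        crit += (np.sqrt(vi.size) + 100.0 * vi.size / n_active
                 + 100.0 * vi.max() + 10.0 * np.sqrt(vi.sum())
                 + 1000.0 * vi.sum() / n_active
                 + 5.0 * zs.max() + 10.0 * np.sqrt(zs.sum())
                 + 100.0 * zs.sum() / n_active)
    return MonotonicityResult(
        item_id, int(n_groups), int(n_active), int(vi.size),
        float(vi.max()) if vi.size else 0.0, float(vi.sum()),
        float(zs.max()) if zs.size else 0.0, float(zs.sum()),
        float(crit), sizes.tolist(), props)


def monotonicity_all(matrix: ResponseMatrix, min_group_size: int | None = None,
                     minvi: float = 0.03,
                     report: ScalabilityReport | None = None) -> pd.DataFrame:
    """Monotonicity table for every item; attaches to ``report`` if given."""
    rep = report or loevinger_coefficients(matrix)
    rows = []
    for iid in matrix.item_ids:
        r = monotonicity_check(matrix, iid, min_group_size, minvi,
                               hj=float(rep.H_j[iid]))
        rows.append({"item": r.item, "n_groups": r.n_groups,
                     "n_active": r.n_active, "n_violations": r.n_violations,
                     "max_violation": r.max_violation, "max_z": r.max_z,
                     "crit": r.crit})
    df = pd.DataFrame(rows)
    if report is not None:
        report.monotonicity = df
    return df
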