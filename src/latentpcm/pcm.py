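"""Partial Credit Model core: probabilities, pairwise conditional estimation,
item locations and EAP person estimates.

The Partial Credit Model (PCM) gives, for an ordinal item j with steps
``delta_j1..delta_jm``, the category probabilities

    P(Y = y | theta) = exp(y*theta - sum_{l<=y} delta_jl) / sum_c exp(...)

with the empty sum for y = 0.  Item thresholds are estimated here by pairwise
conditional estimation (PCE): for every unordered item pair and every person
observing both, the probability of the observed pair given its sum is free of
theta, so the summed log conditional likelihood identifies the thresholds up
to one additive constant, fixed by constraining the sum of all thresholds in
the fitted model to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .questionnaire import ItemSpec, ResponseMatrix

__all__ = [
    "ItemBank",
    "pcm_category_probs",
    "expected_score",
    "estimate_pce",
    "eap_estimate",
]


@dataclass
class ItemBank:
    """Estimated (or true) item thresholds on the logit scale.

    ``thresholds[i]`` is the array ``delta_j1..delta_jm`` of item
    ``item_ids[i]``.  The item location is the mean of its thresholds.
    """

    item_ids: list[str]
    thresholds: list[np.ndarray]
    collapsed: dict[str, list[int]] = field(default_factory=dict)
    converged: bool = True
    grad_norm: float = 0.0

    def __post_init__(self) -> None:
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        for iid, t in zip(self.item_ids, self.thresholds):
            if t.size < 1 or not np.all(np.isfinite(t)):
                raise ValueError(f"item {iid!r}: thresholds must be finite, >=1 step")

    def __getitem__(self, item_id: str) -> np.ndarray:
        return self.thresholds[self.item_ids.index(item_id)]

    @property
    def m(self) -> np.ndarray:
        return np.array([t.size for t in self.thresholds])

    def locations(self) -> pd.Series:
        """Per-item location: mean of the item's thresholds."""
        return pd.Series({iid: float(np.mean(t))
                          for iid, t in zip(self.item_ids, self.thresholds)})

    # -- serialization (item_id, l, delta), 12 significant digits ---------
    def to_csv(self, path) -> None:
        rows = [(iid, l + 1, float(d))
                for iid, t in zip(self.item_ids, self.thresholds)
                for l, d in enumerate(t)]
        pd.DataFrame(rows, columns=["item_id", "l", "delta"]).to_csv(
            path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        df = pd.read_csv(path)
        ids = list(dict.fromkeys(df["item_id"].astype(str)))
        thr = [df.loc[df["item_id"].astype(str) == iid]
                 .sort_values("l")["delta"].to_numpy() for iid in ids]
        return cls(ids, thr)


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------

def _log_probs_grid(theta: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Log category probabilities at each theta; shape (len(theta), m+1)."""
    theta = np.asarray(theta, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(delta)))     # s(y) = sum_{l<=y} delta_l
    y = np.arange(cum.size)
    logits = np.multiply.outer(theta, y) - cum          # (T, m+1)
    return logits - logsumexp(logits, axis=-1, keepdims=True)


def pcm_category_probs(theta: float, delta: np.ndarray) -> np.ndarray:
    """PCM category probability vector of length ``m+1`` at trait ``theta``.

    Stable for |theta| up to ~40 via max-subtraction inside the normalizer.
    """
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("thresholds must be finite")
    return np.exp(_log_probs_grid(np.atleast_1d(float(theta)), delta))[0]


def expected_score(theta: float, delta: np.ndarray) -> float:
    """Model-expected item score ``sum_y y P(Y=y|theta)``; increasing in theta."""
    p = pcm_category_probs(theta, delta)
    return float(p @ np.arange(p.size))


def expected_score_grid(theta: np.ndarray, delta: np.ndarray) -> np.ndarray:
    p = np.exp(_log_probs_grid(theta, delta))
    return p @ np.arange(p.shape[-1])


def score_variance_grid(theta: np.ndarray, delta: np.ndarray) -> np.ndarray:
    p = np.exp(_log_probs_grid(theta, delta))
    y = np.arange(p.shape[-1])
    mu = p @ y
    return p @ (y ** 2) - mu ** 2


# ---------------------------------------------------------------------------
# unobserved-category collapsing
# ---------------------------------------------------------------------------

def collapse_unobserved(
    matrix: ResponseMatrix, m: dict[str, int] | None = None
) -> tuple[ResponseMatrix, dict[str, int], dict[str, list[int]]]:
    """Rebase each item's codes onto consecutively observed categories.

    Categories observed by nobody cannot carry a threshold; they are collapsed
    downward (codes above a gap shift down), a warning is emitted, and the
    mapping old-code -> new-code is returned per recoded item.
    """
    out = matrix.copy()
    new_m: dict[str, int] = {}
    mappings: dict[str, list[int]] = {}
    for j, iid in enumerate(out.item_ids):
        col = out.values[:, j]
        obs = col[~np.isnan(col)].astype(int)
        if obs.size == 0:
            raise ValueError(f"item {iid!r} has no observed responses")
        top = m[iid] if m is not None else int(obs.max())
        seen = np.zeros(top + 1, dtype=bool)
        seen[obs] = True
        if seen.all() and obs.max() > 0:
            new_m[iid] = top
            continue
        mapping = np.cumsum(seen) - 1          # old code -> new rank
        mapping[~seen] = -1
        if seen.sum() < 2:
            raise ValueError(f"item {iid!r}: fewer than 2 observed categories")
        warnings.warn(
            f"item {iid!r}: unobserved categories collapsed "
            f"({top + 1} -> {int(seen.sum())}); codes renumbered", stacklevel=2)
        col[~np.isnan(col)] = mapping[obs]
        new_m[iid] = int(seen.sum()) - 1
        mappings[iid] = mapping.tolist()
    return out, new_m, mappings


# ---------------------------------------------------------------------------
# pairwise conditional estimation
# ---------------------------------------------------------------------------

def _pair_tables(matrix: ResponseMatrix, m: dict[str, int]):
    """Joint count tables n[a, b] per unordered item pair, both observed."""
    tables = {}
    vals = matrix.values
    for j, k in combinations(range(matrix.n_items), 2):
        both = ~np.isnan(vals[:, j]) & ~np.isnan(vals[:, k])
        if not both.any():
            warnings.warn(
                f"items {matrix.item_ids[j]!r}/{matrix.item_ids[k]!r}: no joint "
                "observations; pair dropped", stacklevel=3)
            continue
        a = vals[both, j].astype(int)
        b = vals[both, k].astype(int)
        mj, mk = m[matrix.item_ids[j]], m[matrix.item_ids[k]]
        tab = np.zeros((mj + 1, mk + 1))
        np.add.at(tab, (a, b), 1.0)
        tables[(j, k)] = tab
    return tables


def _pce_objective(delta_flat, tables, offsets, sizes, penalty=1.0):
    """Negative log pairwise conditional likelihood with sum-zero penalty.

    Returns (value, gradient).  For each pair and each total t = a + b the
    conditional distribution over a is an exponential family in the cumulated
    thresholds, so the gradient is counts minus conditional expectations.
    """
    nll = 0.0
    grad = np.zeros_like(delta_flat)
    for (j, k), tab in tables.items():
        dj = delta_flat[offsets[j]: offsets[j] + sizes[j]]
        dk = delta_flat[offsets[k]: offsets[k] + sizes[k]]
        sj = np.concatenate(([0.0], np.cumsum(dj)))      # (mj+1,)
        sk = np.concatenate(([0.0], np.cumsum(dk)))      # (mk+1,)
        mj, mk = sizes[j], sizes[k]
        # first-order terms: sum_ab n_ab (s_j(a) + s_k(b))
        row = tab.sum(axis=1)
        colm = tab.sum(axis=0)
        nll += row @ sj + colm @ sk
        # indicator gradients d s_j(a)/d delta_jl = 1{l <= a}
        grad[offsets[j]: offsets[j] + mj] += np.cumsum(row[::-1])[::-1][1:]
        grad[offsets[k]: offsets[k] + mk] += np.cumsum(colm[::-1])[::-1][1:]
        # conditional normalizers over anti-diagonals t = a + b
        E = -sj[:, None] - sk[None, :]                   # log unnormalized
        for t in range(mj + mk + 1):
            lo, hi = max(0, t - mk), min(t, mj)
            a_idx = np.arange(lo, hi + 1)
            nt = tab[a_idx, t - a_idx].sum()
            if nt == 0.0:
                continue
            e = E[a_idx, t - a_idx]
            mx = e.max()                                 # tiny arrays: manual
            ez = np.exp(e - mx)                          # max-subtraction beats
            sz = ez.sum()                                # generic logsumexp
            nll += nt * (mx + np.log(sz))
            p = ez / sz                                  # P(A = a | t)
            # d logZ / d delta_jl = -P(A >= l | t), l = 1..mj
            pa = np.zeros(mj + 1)
            pa[a_idx] = p
            tail = np.cumsum(pa[::-1])[::-1]             # P(A >= code)
            grad[offsets[j]: offsets[j] + mj] -= nt * tail[1:]
            # item k: b = t - a, P(B >= l | t)
            pb = np.zeros(mk + 1)
            pb[t - a_idx] = p
            tailb = np.cumsum(pb[::-1])[::-1]
            grad[offsets[k]: offsets[k] + mk] -= nt * tailb[1:]
    s = delta_flat.sum()
    nll += penalty * s * s
    grad += 2.0 * penalty * s
    return nll, grad


def estimate_pce(
    matrix: ResponseMatrix,
    items: list[ItemSpec] | None = None,
    tol: float = 1e-9,
) -> ItemBank:
    """Estimate PCM thresholds by pairwise conditional estimation.

    Identifiability is fixed by the sum-zero constraint over all thresholds of
    the fitted model, so stratum-wise locations are comparable as relative
    quantities.  Unobserved categories are collapsed (with a warning and a
    recorded mapping) before estimation.
    """
    if matrix.n_items < 2:
        raise ValueError("PCE needs at least 2 items")
    m0 = {s.item_id: s.m for s in items} if items is not None else None
    work, m, mappings = collapse_unobserved(matrix, m0)
    sizes = [m[iid] for iid in work.item_ids]
    offsets = np.concatenate(([0], np.cumsum(sizes[:-1]))).astype(int)
    tables = _pair_tables(work, m)
    if not tables:
        raise ValueError("no item pair has joint observations")
    x0 = np.zeros(int(np.sum(sizes)))
    res = minimize(_pce_objective, x0, args=(tables, offsets, sizes),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": tol, "gtol": 1e-7})
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > 1e-3:
        warnings.warn(f"PCE did not converge: {res.message} "
                      f"(max |gradient| = {gnorm:.2e})", stacklevel=2)
    delta = res.x - res.x.mean()        # exact sum-zero (flat direction)
    thr = [delta[o: o + s] for o, s in zip(offsets, sizes)]
    return ItemBank(list(work.item_ids), thr, collapsed=mappings,
                    converged=bool(res.success), grad_norm=gnorm)


def pairwise_conditional_loglik(matrix: ResponseMatrix, bank: ItemBank) -> float:
    """Log pairwise conditional likelihood of the data under ``bank``.

    Exposed for oracle testing: on tiny matrices it can be checked against
    brute-force enumeration of conditional outcomes.
    """
    m = {iid: t.size for iid, t in zip(bank.item_ids, bank.thresholds)}
    sizes = [m[iid] for iid in matrix.item_ids]
    offsets = np.concatenate(([0], np.cumsum(sizes[:-1]))).astype(int)
    tables = _pair_tables(matrix, m)
    flat = np.concatenate([bank[iid] for iid in matrix.item_ids])
    nll, _ = _pce_objective(flat, tables, offsets, sizes, penalty=0.0)
    return -float(nll)


# ---------------------------------------------------------------------------
# EAP person estimates
# ---------------------------------------------------------------------------

def eap_estimate(
    matrix: ResponseMatrix,
    bank: ItemBank,
    prior_mean: float = 0.0,
    prior_var: float = 1.0,
    n_nodes: int = 61,
) -> np.ndarray:
    """Expected a posteriori trait estimates under a Normal prior.

    Gauss-Hermite quadrature with ``n_nodes`` nodes; persons with no observed
    response get NaN.
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    theta = prior_mean + np.sqrt(2.0 * prior_var) * x      # (Q,)
    logw = np.log(w)
    n = matrix.n_persons
    loglik = np.zeros((n, n_nodes))
    for iid in matrix.item_ids:
        if iid not in bank.item_ids:
            raise ValueError(f"item {iid!r} missing from bank")
        col = matrix.column(iid)
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        lp = _log_probs_grid(theta, bank[iid])             # (Q, m+1)
        loglik[obs] += lp[:, col[obs].astype(int)].T
    post = logw[None, :] + loglik
    post -= logsumexp(post, axis=1, keepdims=True)
    est = np.exp(post) @ theta
    est[~matrix.observed().any(axis=1)] = np.nan
    return est
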