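"""Global item-trait interaction fit test for a calibrated PCM.

Each item is tested by splitting persons into class intervals along the trait
and comparing observed with model-expected scores.  To keep the null
distribution honest, the conditioning for item j uses only the OTHER items:
persons are grouped by their rest-posterior trait estimate, and the expected
score and its variance are posterior moments given the rest responses.  Given
the rest of the response vector, the observed score of item j then has exactly
the computed conditional mean, so the per-interval standardized sums are
asymptotically standard normal and the per-item statistic is chi-squared with
one degree of freedom per interval.

Large-sample tests detect tiny irrelevant misfit; the companion rescaling
deflates the statistic to a moderate effective sample size N0 by multiplying
it by N0/N before recomputing the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .pcm import ItemBank, _log_probs_grid
from .questionnaire import ResponseMatrix

__all__ = ["FitTestResult", "item_trait_chisq", "rescale_statistic"]


@dataclass
class FitTestResult:
    per_item: pd.DataFrame          # item, chisq, df, p
    chisq: float
    df: int
    p: float
    n: int
    note: str = ""


def item_trait_chisq(
    matrix: ResponseMatrix,
    bank: ItemBank,
    n_class_intervals: int = 10,
    prior_mean: float = 0.0,
    prior_var: float = 1.0,
    n_nodes: int = 61,
    min_interval_size: int = 20,
) -> FitTestResult:
    """Item-trait chi-squared fit test against the calibrated bank.

    ``prior_mean``/``prior_var`` are the calibrated latent distribution.
    Intervals with fewer than ``min_interval_size`` persons are merged with
    their neighbor.  With a single interval per item the test is undefined and
    reported as such.
    """
    matrix = matrix.drop_empty_persons()
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    theta = prior_mean + np.sqrt(2.0 * prior_var) * x
    logw = np.log(w) - 0.5 * np.log(np.pi)
    n, J = matrix.n_persons, matrix.n_items

    item_lp = []          # per item: (rows, codes, loglik (nobs, Q))
    total = np.zeros((n, n_nodes))
    for iid in matrix.item_ids:
        col = matrix.column(iid)
        rows = np.nonzero(~np.isnan(col))[0]
        codes = col[rows].astype(int)
        lp = _log_probs_grid(theta, bank[iid])            # (Q, m+1)
        contrib = lp[:, codes].T                          # (nobs, Q)
        total[rows] += contrib
        item_lp.append((rows, codes, contrib))

    recs = []
    grand = 0.0
    grand_df = 0
    for iid, (rows, codes, contrib) in zip(matrix.item_ids, item_lp):
        rest = logw[None, :] + total[rows] - contrib      # exclude item j
        rest -= logsumexp(rest, axis=1, keepdims=True)
        W = np.exp(rest)                                  # (nobs, Q)
        delta = bank[iid]
        y = np.arange(delta.size + 1)
        p_grid = np.exp(_log_probs_grid(theta, delta))    # (Q, m+1)
        s_grid = p_grid @ y
        v_grid = p_grid @ (y ** 2) - s_grid ** 2
        e = W @ s_grid                                    # E[Y | rest]
        v = W @ (v_grid + s_grid ** 2) - e ** 2           # Var[Y | rest]
        # rest-EAP used only to order persons into class intervals.  It is
        # quantized so persons with identical rest patterns tie exactly and
        # the stable sort falls back to person order: the float residue of
        # computing the rest log-likelihood as (total - own contribution)
        # depends on the person's own response, and letting it break ties
        # would order persons within a tie block by their observed score,
        # biasing the interval sums.
        theta_hat = np.round(W @ theta, 9)
        n_obs = rows.size
        # multi-item persons only: with no rest information the conditional
        # moments are the prior's, which is still valid, so keep everyone
        order = np.argsort(theta_hat, kind="stable")
        G = max(1, min(n_class_intervals, n_obs // max(min_interval_size, 1)))
        bounds = np.linspace(0, n_obs, G + 1).astype(int)
        chisq = 0.0
        used = 0
        for g in range(G):
            sel = order[bounds[g]:bounds[g + 1]]
            if sel.size == 0:
                continue
            vs = v[sel].sum()
            if vs <= 0:
                continue
            z = (codes[sel] - e[sel]).sum() / np.sqrt(vs)
            chisq += z * z
            used += 1
        if used < 2:
            recs.append({"item": iid, "chisq": np.nan, "df": 0, "p": np.nan})
            continue
        recs.append({"item": iid, "chisq": chisq, "df": used,
                     "p": chi2.sf(chisq, used)})
        grand += chisq
        grand_df += used
    per_item = pd.DataFrame(recs)
    if grand_df == 0:
        return FitTestResult(per_item, np.nan, 0, np.nan, n,
                             note="test undefined: fewer than 2 intervals")
    return FitTestResult(per_item, float(grand), int(grand_df),
                         float(chi2.sf(grand, grand_df)), n)


def rescale_statistic(chisq: float, n: int, df: int,
                      n0: int = 500) -> tuple[float, float, str]:
    """Deflate a chi-squared statistic to effective sample size ``n0``.

    Returns (scaled statistic, p-value at unchanged df, note).  For n < n0 the
    statistic is returned unchanged with a note.
    """
    if n < n0:
        return float(chisq), float(chi2.sf(chisq, df)), \
            f"n = {n} < n0 = {n0}; statistic unchanged"
    scaled = chisq * n0 / n
    return float(scaled), float(chi2.sf(scaled, df)), ""
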