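"""Latent-regression mixed Partial Credit Model.

The measurement part is a PCM with thresholds frozen at calibrated values; the
structural part lets person covariates explain both moments of the latent
trait:

    theta_n ~ Normal(mu_n, sigma2_n),
    mu_n     = mu* + X_n beta,
    sigma2_n = sigma2* + Z_n gamma,

where mu* and sigma2* are the mean and variance of the reference group (all
design columns zero).  The marginal likelihood integrates the trait out with
Gauss-Hermite quadrature centered and scaled per person; coefficients are
estimated by maximum likelihood with Wald standard errors from the observed
information.  Model selection removes non-significant terms backwards under an
AIC guard, mean model first, then variance model.

The explained-variance rate compares the latent variance with and without
covariates, adjusted for parameter counts:

    tau = 1 - [(n - 1 - k) sigma2_hat] / [(n - 1 - k0) sigma2_hat_0].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .design import Effect, build_design, profile_row
from .pcm import ItemBank, estimate_pce
from .questionnaire import ItemSpec, ResponseMatrix

__all__ = [
    "LatentRegressionFit",
    "AgeRecoding",
    "calibrate_items",
    "fit_mixed_pcm",
    "backward_select",
    "explained_variance_tau",
    "recode_age_quantitative",
    "profile_deviation",
]

_SQRT2 = np.sqrt(2.0)
_VAR_FLOOR = 1e-3


@dataclass
class LatentRegressionFit:
    """Estimated latent-regression mixed PCM (or a published table of one)."""

    mu_star: float
    sigma2_star: float
    mean_effects: list[Effect]
    beta: np.ndarray
    var_effects: list[Effect] = field(default_factory=list)
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    se: np.ndarray | None = None          # [mu*, beta, sigma2*, gamma]
    pvalues: np.ndarray | None = None
    loglik: float = np.nan
    n: int = 0
    k: int = 0
    converged: bool = True
    boundary: bool = False

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def mean_at(self, profile: dict) -> float:
        return self.mu_star + profile_row(self.mean_effects, profile) @ self.beta

    def variance_at(self, profile: dict) -> float:
        return self.sigma2_star + profile_row(self.var_effects, profile) @ self.gamma

    def coef_table(self) -> pd.DataFrame:
        labels = (["Constant (mu*)"] + [e.label for e in self.mean_effects]
                  + ["Constant (sigma2*)"] + [e.label for e in self.var_effects])
        section = (["mean"] * (1 + len(self.beta))
                   + ["variance"] * (1 + len(self.gamma)))
        est = np.concatenate(([self.mu_star], self.beta,
                              [self.sigma2_star], self.gamma))
        df = pd.DataFrame({"section": section, "term": labels, "estimate": est})
        if self.se is not None:
            df["se"] = self.se
            df["p"] = self.pvalues
        return df


@dataclass(frozen=True)
class AgeRecoding:
    """Integer scores turning an ordinal age factor into a quantitative one."""

    bands: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s[0] != 0 or np.any(s < 0) or np.any(np.diff(s) < 0):
            raise ValueError("scores must start at 0 and be nondecreasing")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.bands, self.scores))


# ---------------------------------------------------------------------------
# item-likelihood plumbing shared by calibration and regression
# ---------------------------------------------------------------------------

def _item_arrays(matrix: ResponseMatrix, bank: ItemBank):
    """Per item: (row indices of observing persons, int codes, thresholds)."""
    out = []
    for iid in matrix.item_ids:
        col = matrix.column(iid)
        obs = np.nonzero(~np.isnan(col))[0]
        out.append((obs, col[obs].astype(int), np.asarray(bank[iid], float)))
    return out


def _accumulate_loglik(theta: np.ndarray, rows, codes, delta,
                       L: np.ndarray, S: np.ndarray) -> None:
    """Add item j's observed log-probabilities into L and its score residuals
    ``y - E[Y|theta]`` into S, at per-person node matrix ``theta`` (N, Q)."""
    cum = np.concatenate(([0.0], np.cumsum(delta)))
    y = np.arange(cum.size)
    t = theta[rows]                                    # (nobs, Q)
    logits = t[:, :, None] * y - cum                   # (nobs, Q, m+1)
    lse = logsumexp(logits, axis=2)
    L[rows] += np.take_along_axis(
        logits, codes[:, None, None].repeat(t.shape[1], axis=1), axis=2
    )[:, :, 0] - lse
    p = np.exp(logits - lse[:, :, None])
    S[rows] += codes[:, None] - p @ y


# ---------------------------------------------------------------------------
# calibration: marginal ML with theta ~ N(0, sigma2), thresholds free
# ---------------------------------------------------------------------------

def calibrate_items(
    matrix: ResponseMatrix,
    items: list[ItemSpec] | None = None,
    n_nodes: int = 21,
    start_from_pce: bool = True,
) -> tuple[ItemBank, float, dict]:
    """Joint marginal-ML fit of all thresholds and the latent variance.

    The latent mean is fixed at 0 for identifiability; the trait is integrated
    out by Gauss-Hermite quadrature.  Returns the calibrated bank (to be
    FROZEN in subsequent latent-regression fits), the variance estimate, and
    fit information (loglik, n, k, convergence).
    """
    matrix = matrix.drop_empty_persons()
    if matrix.n_items < 2:
        raise ValueError("calibration needs at least 2 items (unidentifiable)")
    if start_from_pce:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank0 = estimate_pce(matrix, items)
    else:
        from .pcm import collapse_unobserved
        work, m, _ = collapse_unobserved(
            matrix, {s.item_id: s.m for s in items} if items else None)
        matrix = work
        bank0 = ItemBank(list(matrix.item_ids),
                         [np.zeros(m[iid]) for iid in matrix.item_ids])
    ids = bank0.item_ids
    sizes = [t.size for t in bank0.thresholds]
    offsets = np.concatenate(([0], np.cumsum(sizes[:-1]))).astype(int)
    D = int(np.sum(sizes))
    # matrix may have been re-collapsed inside PCE; re-read codes against bank0
    per_item = _item_arrays(matrix, bank0)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(w) - 0.5 * np.log(np.pi)
    n = matrix.n_persons

    def nll_grad(params):
        delta = params[:D]
        sigma = np.exp(0.5 * params[D])
        theta_q = _SQRT2 * sigma * x                     # (Q,)
        L = np.zeros((n, n_nodes))
        grads = np.zeros_like(params)
        tails, escores, wsums = [], [], []
        for (rows, codes, _), off, size in zip(per_item, offsets, sizes):
            cum = np.concatenate(([0.0], np.cumsum(delta[off:off + size])))
            y = np.arange(size + 1)
            logits = np.multiply.outer(theta_q, y) - cum  # (Q, m+1)
            lse = logsumexp(logits, axis=1)
            lp = logits - lse[:, None]
            L[rows] += lp[:, codes].T
            p = np.exp(lp)
            tails.append(np.cumsum(p[:, ::-1], axis=1)[:, ::-1])  # P(C>=c)
            escores.append(p @ y)
        logpost = logw[None, :] + L
        ll = logsumexp(logpost, axis=1)
        W = np.exp(logpost - ll[:, None])                # posterior weights
        dsig = 0.0
        for (rows, codes, _), off, size, tail, esc in zip(
                per_item, offsets, sizes, tails, escores):
            Wobs = W[rows]                               # (nobs, Q)
            wsum_code = np.zeros((size + 1, n_nodes))
            np.add.at(wsum_code, codes, Wobs)            # sum_n W over code c
            tot = wsum_code.sum(axis=0)                  # (Q,)
            ge = np.cumsum(wsum_code[::-1], axis=0)[::-1]  # sum_{c>=l}
            grads[off:off + size] = (ge[1:] - tot * tail.T[1:]).sum(axis=1)
            dsig += ((Wobs * (codes[:, None] - esc[None, :])).sum(axis=0)
                     * _SQRT2 * x).sum()
        grads[D] = -dsig * sigma / 2.0                   # wrt log sigma2
        return -float(ll.sum()), grads

    x0 = np.concatenate([np.concatenate(bank0.thresholds), [0.0]])
    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-11, "gtol": 1e-6})
    if not res.success:
        warnings.warn(f"calibration did not converge: {res.message}",
                      stacklevel=2)
    delta = res.x[:D]
    sigma2 = float(np.exp(res.x[D]))
    bank = ItemBank(ids, [delta[o:o + s] for o, s in zip(offsets, sizes)],
                    collapsed=bank0.collapsed, converged=bool(res.success))
    info = {"loglik": -float(res.fun), "n": n, "k": D + 1,
            "aic": 2.0 * (D + 1) + 2.0 * float(res.fun),
            "converged": bool(res.success)}
    return bank, sigma2, info


# ---------------------------------------------------------------------------
# latent regression with frozen thresholds
# ---------------------------------------------------------------------------

def _mixed_nll_grad(params, X, Z, per_item, x, logw, n, var_floor=_VAR_FLOOR,
                    barrier=1e4):
    P, Q = X.shape[1], Z.shape[1]
    mu_star, beta = params[0], params[1:1 + P]
    s2_star, gamma = params[1 + P], params[2 + P:]
    mu = mu_star + X @ beta
    s2_raw = s2_star + Z @ gamma
    s2 = np.maximum(s2_raw, var_floor)
    pen = barrier * np.sum((s2_raw - s2) ** 2)
    dpen = 2.0 * barrier * (s2_raw - s2)
    sig = np.sqrt(s2)
    theta = mu[:, None] + _SQRT2 * sig[:, None] * x[None, :]   # (N, Qnodes)
    L = np.zeros_like(theta)
    S = np.zeros_like(theta)
    for rows, codes, delta in per_item:
        _accumulate_loglik(theta, rows, codes, delta, L, S)
    logpost = logw[None, :] + L
    ll = logsumexp(logpost, axis=1)
    W = np.exp(logpost - ll[:, None])
    g_mu = (W * S).sum(axis=1)                                 # dll/dmu_n
    g_sig = (W * S * (_SQRT2 * x)[None, :]).sum(axis=1)        # dll/dsigma_n
    g_s2 = np.where(s2_raw > var_floor, g_sig / (2.0 * sig), 0.0) - dpen
    grad = np.empty_like(params)
    grad[0] = -g_mu.sum()
    grad[1:1 + P] = -(X.T @ g_mu)
    grad[1 + P] = -g_s2.sum()
    grad[2 + P:] = -(Z.T @ g_s2)
    return -float(ll.sum()) + pen, grad


def fit_mixed_pcm(
    matrix: ResponseMatrix,
    bank: ItemBank,
    covariates: pd.DataFrame,
    mean_effects: list[Effect],
    var_effects: list[Effect] | None = None,
    n_nodes: int = 21,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> LatentRegressionFit:
    """Maximize the marginal likelihood over (mu*, beta, sigma2*, gamma).

    Thresholds come frozen from ``bank``.  The quadrature is Gauss-Hermite
    centered at mu_n and scaled by sigma_n for each person.  A variance model
    touching the positivity floor marks the fit ``boundary`` (invalid) with
    the offending covariate pattern reported in a warning.
    """
    var_effects = var_effects or []
    if len(covariates) != matrix.n_persons:
        raise ValueError("covariate table not aligned with response matrix")
    keep = matrix.observed().any(axis=1)
    cov = covariates.iloc[np.nonzero(keep)[0]]
    matrix = matrix.drop_empty_persons()
    X = build_design(cov, mean_effects)
    Z = build_design(cov, var_effects)
    for name, M in (("mean", np.column_stack([np.ones(len(cov)), X])),
                    ("variance", np.column_stack([np.ones(len(cov)), Z]))):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError(f"{name}-model design is rank deficient")
    per_item = _item_arrays(matrix, bank)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(w) - 0.5 * np.log(np.pi)
    n = matrix.n_persons
    P, Q = X.shape[1], Z.shape[1]
    if start is None:
        start = np.zeros(2 + P + Q)
        start[1 + P] = 1.0                       # sigma2* start
    args = (X, Z, per_item, x, logw, n)
    res = minimize(_mixed_nll_grad, start, args=args, jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-11, "gtol": 1e-6})
    if not res.success:
        warnings.warn(f"latent regression did not converge: {res.message}",
                      stacklevel=2)
    p = res.x
    s2_fit = p[1 + P] + Z @ p[2 + P:]
    boundary = bool(np.min(s2_fit) <= _VAR_FLOOR * 1.01)
    if boundary:
        bad = cov.iloc[int(np.argmin(s2_fit))]
        warnings.warn(
            "variance model reached the positivity boundary for pattern "
            f"{bad.to_dict()}; fit flagged invalid", stacklevel=2)
    se = pvals = None
    if compute_se:
        eps = 1e-5 * np.maximum(1.0, np.abs(p))
        H = np.empty((p.size, p.size))
        for i in range(p.size):
            dp = np.zeros_like(p)
            dp[i] = eps[i]
            gp = _mixed_nll_grad(p + dp, *args)[1]
            gm = _mixed_nll_grad(p - dp, *args)[1]
            H[i] = (gp - gm) / (2.0 * eps[i])
        H = (H + H.T) / 2.0
        try:
            cov_p = np.linalg.inv(H)
            d = np.diag(cov_p).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
            pvals = 2.0 * norm.sf(np.abs(p / se))
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; no standard errors",
                          stacklevel=2)
    return LatentRegressionFit(
        mu_star=float(p[0]), sigma2_star=float(p[1 + P]),
        mean_effects=list(mean_effects), beta=p[1:1 + P],
        var_effects=list(var_effects), gamma=p[2 + P:],
        se=se, pvalues=pvals, loglik=-float(res.fun),
        n=n, k=2 + P + Q, converged=bool(res.success), boundary=boundary)


# ---------------------------------------------------------------------------
# backward selection
# ---------------------------------------------------------------------------

def _removable(effects: list[Effect]) -> list[int]:
    """Interactions are always removable; a main effect only when no retained
    interaction involves its variable."""
    locked: set[str] = set()
    for e in effects:
        if e.order > 1:
            locked |= e.variables
    out = []
    for i, e in enumerate(effects):
        if e.order > 1 or not (e.variables & locked):
            out.append(i)
    return out


def backward_select(
    matrix: ResponseMatrix,
    bank: ItemBank,
    covariates: pd.DataFrame,
    mean_candidates: list[Effect],
    var_candidates: list[Effect] | None = None,
    alpha: float = 0.05,
    n_nodes: int = 21,
) -> tuple[LatentRegressionFit, list[dict]]:
    """Backward elimination at level ``alpha`` under an AIC guard.

    Mean-model terms are selected first (variance model empty), then variance
    terms with the selected mean model held.  Each round removes the least
    significant removable term with p >= alpha whose removal does not increase
    AIC; ties favour the largest p.  Returns the final fit and a removal log.
    """
    var_candidates = list(var_candidates or [])
    log: list[dict] = []

    def params_of(fit):
        return np.concatenate(([fit.mu_star], fit.beta,
                               [fit.sigma2_star], fit.gamma))

    def drop_param(fit, stage, i):
        p = params_of(fit)
        idx = 1 + i if stage == "mean" else 2 + len(fit.beta) + i
        return np.delete(p, idx)

    def select(mean_eff, var_eff, stage):
        # trial fits skip the (expensive) observed-information step and warm
        # start from the current optimum; SEs are refreshed on acceptance
        mean_eff, var_eff = list(mean_eff), list(var_eff)
        fit = fit_mixed_pcm(matrix, bank, covariates, mean_eff, var_eff,
                            n_nodes=n_nodes, compute_se=True)
        while True:
            pool = mean_eff if stage == "mean" else var_eff
            if not pool or fit.pvalues is None:
                break
            base = 1 if stage == "mean" else 2 + len(mean_eff)
            pv = fit.pvalues[base:base + len(pool)]
            cand = [(i, pv[i]) for i in _removable(pool)
                    if np.isfinite(pv[i]) and pv[i] >= alpha]
            cand.sort(key=lambda t: -t[1])
            removed = False
            for i, p in cand:
                trial_mean = [e for j, e in enumerate(mean_eff)
                              if not (stage == "mean" and j == i)]
                trial_var = [e for j, e in enumerate(var_eff)
                             if not (stage == "variance" and j == i)]
                start = drop_param(fit, stage, i)
                trial = fit_mixed_pcm(matrix, bank, covariates, trial_mean,
                                      trial_var, n_nodes=n_nodes,
                                      start=start, compute_se=False)
                if trial.aic <= fit.aic:
                    log.append({"stage": stage, "term": pool[i].label,
                                "p": float(p), "aic_before": fit.aic,
                                "aic_after": trial.aic})
                    mean_eff, var_eff = trial_mean, trial_var
                    fit = fit_mixed_pcm(matrix, bank, covariates, mean_eff,
                                        var_eff, n_nodes=n_nodes,
                                        start=params_of(trial),
                                        compute_se=True)
                    removed = True
                    break
            if not removed:
                break
        return mean_eff, var_eff, fit

    mean_sel, _, _ = select(mean_candidates, [], "mean")
    mean_sel, var_sel, fit = select(mean_sel, var_candidates, "variance")
    return fit, log


# ---------------------------------------------------------------------------
# explained variance, age recoding, profile contrasts
# ---------------------------------------------------------------------------

def explained_variance_tau(sigma0_sq: float, k0: int, sigma_sq: float, k: int,
                           n: int) -> float:
    """Explained-variance rate comparing latent variance with and without
    covariates, adjusted for parameter counts:

        tau = 1 - [(n - 1 - k) sigma_sq] / [(n - 1 - k0) sigma0_sq].
    """
    if sigma0_sq <= 0 or sigma_sq <= 0:
        raise ValueError("variances must be positive")
    if n <= max(k, k0) + 1:
        raise ValueError("n must exceed max(k, k0) + 1")
    return 1.0 - ((n - 1 - k) * sigma_sq) / ((n - 1 - k0) * sigma0_sq)


def _pav_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto nondecreasing sequences."""
    vals = y.astype(float).tolist()
    wts = [1.0] * len(vals)
    out_v, out_w = [], []
    for v, wt in zip(vals, wts):
        out_v.append(v)
        out_w.append(wt)
        while len(out_v) > 1 and out_v[-2] > out_v[-1]:
            v2 = (out_v[-2] * out_w[-2] + out_v[-1] * out_w[-1]) / (out_w[-2] + out_w[-1])
            w2 = out_w[-2] + out_w[-1]
            out_v[-2:] = [v2]
            out_w[-2:] = [w2]
    res = []
    for v, wt in zip(out_v, out_w):
        res += [v] * int(round(wt))
    return np.array(res)


def recode_age_quantitative(
    coefficients,
    bands: list[str] | None = None,
    round_to_int: bool = True,
    isotonic: bool = False,
) -> AgeRecoding:
    """Turn fitted age-band dummy coefficients into integer age scores.

    The reference band scores 0; the remaining scores are the coefficients
    divided by the smallest-magnitude nonzero coefficient (the per-unit
    trend), rounded to integers.  A non-monotone coefficient pattern triggers
    a warning; with ``isotonic=True`` it is first projected onto a monotone
    sequence.  Whether the quantitative recoding is retained is decided by an
    AIC comparison against the dummy fit, outside this function.
    """
    if isinstance(coefficients, pd.Series):
        bands = bands or list(coefficients.index.astype(str))
        coefs = coefficients.to_numpy(dtype=float)
    else:
        coefs = np.asarray(coefficients, dtype=float)
        bands = bands or [str(i) for i in range(coefs.size)]
    if coefs[0] != 0.0:
        raise ValueError("reference band must have coefficient 0")
    nonzero = coefs[coefs != 0.0]
    if nonzero.size == 0:
        raise ValueError("all-zero coefficients: recoding refused")
    unit = nonzero[np.argmin(np.abs(nonzero))]
    scores = coefs / unit
    if np.any(np.diff(scores) < 0):
        warnings.warn("non-monotone age coefficients", stacklevel=2)
        if isotonic:
            scores = _pav_nondecreasing(scores)
            scores -= scores[0]
        else:
            raise ValueError(
                "non-monotone coefficient pattern; pass isotonic=True to "
                "project onto a monotone sequence")
    if round_to_int:
        # the unit coefficient is only identified up to a rational factor:
        # pick the smallest integer multiplier under which every score sits
        # close to an integer (e.g. half-integer patterns double cleanly)
        for mult in range(1, 7):
            cand = scores * mult
            if np.max(np.abs(cand - np.round(cand))) <= 0.25:
                scores = np.round(cand)
                break
        else:
            scores = np.round(scores)
    return AgeRecoding(tuple(bands), tuple(float(s) + 0.0 for s in scores))


def profile_deviation(fit: LatentRegressionFit, profile: dict,
                      reference: dict, component: str = "mean") -> float:
    """Difference of modeled latent mean (or variance) between two covariate
    profiles; the constant cancels."""
    effects, coefs = ((fit.mean_effects, fit.beta) if component == "mean"
                      else (fit.var_effects, fit.gamma))
    return float((profile_row(effects, profile)
                  - profile_row(effects, reference)) @ coefs)
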