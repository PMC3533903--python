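"""Synthetic questionnaire data with the structure the analysis assumes.

The generator draws person covariates, a latent trait whose mean AND variance
are linear in covariate designs, PCM responses given the trait (optionally
with group-specific threshold shifts, i.e. true DIF), and missingness that is
either completely at random or informative (probability increasing as the
trait decreases).  It is the ground-truth test bed for every downstream stage:
threshold recovery, DIF detection operating characteristics, latent-regression
recovery, and fit-test calibration.

Default conditions emulate the French general-population SF-36 surveys the
analysis was designed for: two survey years with very unequal sizes, seven age
bands, nine regions with the published regional distribution, and a slight
excess of women.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import Effect, build_design
from .questionnaire import ItemSpec, ResponseMatrix

__all__ = [
    "FactorSpec",
    "SimulationConfig",
    "simulate_covariates",
    "simulate_latent",
    "simulate_responses",
    "apply_missingness",
    "simulate_dataset",
    "default_items",
    "default_config",
]


@dataclass(frozen=True)
class FactorSpec:
    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError(f"factor {self.name!r}: levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-8:
            raise ValueError(f"factor {self.name!r}: probabilities must sum to 1")


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic dataset."""

    n: int
    items: list[ItemSpec]
    thresholds: dict[str, np.ndarray]
    factors: list[FactorSpec] = field(default_factory=list)
    mu_star: float = 0.0
    sigma2_star: float = 1.0
    beta: list[tuple[Effect, float]] = field(default_factory=list)
    gamma: list[tuple[Effect, float]] = field(default_factory=list)
    quantitative: dict[str, dict[str, float]] = field(default_factory=dict)
    # recoded numeric columns derived from a factor: column -> {level: score}
    dif_offsets: dict[tuple[str, str, str], float] = field(default_factory=dict)
    # (item_id, factor, level) -> additive shift of ALL the item's thresholds
    missingness: tuple = ("none",)
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_covariates(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw person covariates, independently across factors."""
    rng = rng or config.rng()
    data: dict[str, np.ndarray] = {
        "person_id": np.arange(config.n)}
    for f in config.factors:
        data[f.name] = rng.choice(f.levels, size=config.n, p=f.probs)
    df = pd.DataFrame(data)
    for col, scores in config.quantitative.items():
        factor = next(f for f in config.factors
                      if set(f.levels) == set(scores))
        df[col] = df[factor.name].map(scores).astype(float)
    return df


def simulate_latent(config: SimulationConfig, covariates: pd.DataFrame,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw theta_n ~ Normal(mu* + X_n beta, sigma2* + Z_n gamma)."""
    rng = rng or config.rng()
    X = build_design(covariates, [e for e, _ in config.beta])
    Z = build_design(covariates, [e for e, _ in config.gamma])
    mu = config.mu_star + X @ np.array([b for _, b in config.beta])
    s2 = config.sigma2_star + Z @ np.array([g for _, g in config.gamma])
    if np.any(s2 <= 0):
        bad = covariates.iloc[int(np.argmax(s2 <= 0))]
        raise ValueError(
            f"non-positive latent variance ({s2.min():.4f}) for covariate "
            f"pattern {bad.to_dict()}")
    return mu + np.sqrt(s2) * rng.standard_normal(config.n)


def simulate_responses(
    theta: np.ndarray,
    items: list[ItemSpec],
    thresholds: dict[str, np.ndarray],
    covariates: pd.DataFrame | None = None,
    dif_offsets: dict[tuple[str, str, str], float] | None = None,
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Draw PCM responses at each person's trait and effective thresholds.

    A DIF offset shifts every threshold of the item by a constant for persons
    at the given factor level, which lowers the item's expected score for that
    group at equal trait (positive shift = harder item).
    """
    rng = rng or np.random.default_rng()
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    cols = []
    for spec in items:
        delta = np.asarray(thresholds[spec.item_id], dtype=float)
        if delta.size != spec.m:
            raise ValueError(f"item {spec.item_id!r}: expected {spec.m} thresholds")
        if not np.all(np.isfinite(delta)):
            raise ValueError(f"item {spec.item_id!r}: thresholds must be finite")
        offset = np.zeros(n)
        if dif_offsets:
            for (iid, factor, level), shift in dif_offsets.items():
                if iid == spec.item_id:
                    if covariates is None:
                        raise ValueError("dif_offsets given without covariates")
                    mask = covariates[factor].astype(str).to_numpy() == str(level)
                    offset[mask] += shift
        # shifting all thresholds by o equals shifting theta by -o
        cum = np.concatenate(([0.0], np.cumsum(delta)))
        y = np.arange(spec.m + 1)
        logits = np.multiply.outer(theta - offset, y) - cum
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cols.append((p.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float))
    return ResponseMatrix(np.column_stack(cols), np.arange(n),
                          [s.item_id for s in items])


def apply_missingness(
    matrix: ResponseMatrix,
    theta: np.ndarray,
    mechanism: tuple,
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Blank out responses per the configured mechanism.

    ``("none",)`` — identity; ``("mcar", rate)`` — each cell independently
    missing; ``("informative", slope, rate)`` — cell missing with probability
    ``logistic(a - slope * theta_n)``, the intercept ``a`` calibrated so the
    expected overall missing fraction equals ``rate``.
    """
    rng = rng or np.random.default_rng()
    kind = mechanism[0]
    if kind == "none":
        return matrix.copy()
    out = matrix.copy()
    if kind == "mcar":
        rate = float(mechanism[1])
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"mcar rate must be in [0, 1), got {rate}")
        mask = rng.random(out.values.shape) < rate
    elif kind == "informative":
        slope, rate = float(mechanism[1]), float(mechanism[2])
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"target rate must be in [0, 1), got {rate}")
        if rate == 0.0:
            return out

        def mean_rate(a):
            return expit(a - slope * theta).mean() - rate

        a = brentq(mean_rate, -50, 50)
        p = expit(a - slope * theta)
        mask = rng.random(out.values.shape) < p[:, None]
    else:
        raise ValueError(f"unknown missingness mechanism {kind!r}")
    out.values[mask] = np.nan
    return out


def simulate_dataset(config: SimulationConfig):
    """Covariates, latent trait and response matrix in one reproducible call."""
    rng = config.rng()
    cov = simulate_covariates(config, rng)
    theta = simulate_latent(config, cov, rng)
    resp = simulate_responses(theta, config.items, config.thresholds,
                              cov, config.dif_offsets, rng)
    resp = apply_missingness(resp, theta, config.missingness, rng)
    return resp, cov, theta


# ---------------------------------------------------------------------------
# default study-like conditions
# ---------------------------------------------------------------------------

AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84")
REGIONS = ("Paris Basin", "North", "East", "Eastern Paris Basin",
           "Western Paris Basin", "West", "South-West", "South-East",
           "Mediterranean Basin")


def default_items(n_items: int = 5, n_categories: int = 4,
                  spread: float = 1.0) -> tuple[list[ItemSpec], dict]:
    """A bank of polytomous items with locations evenly spread in ±``spread``
    and within-item steps at location ± 1."""
    items, thr = [], {}
    locs = np.linspace(-spread, spread, n_items)
    m = n_categories - 1
    steps = np.linspace(-1.0, 1.0, m) if m > 1 else np.array([0.0])
    for i, loc in enumerate(locs):
        iid = f"I{i + 1}"
        items.append(ItemSpec(iid, n_categories))
        thr[iid] = loc + steps
    return items, thr


def default_config(n: int = 5000, seed: int = 0, **overrides) -> SimulationConfig:
    """Survey-like default conditions.

    Gender 46.5/53.5, seven age bands, the nine-region distribution of the
    French surveys (21/10/8/15/7/11/8/9/11 percent), and two survey years with
    sizes in the observed 13.9/86.1 ratio.  Five 4-category items; no effects,
    no DIF, no missingness unless overridden.
    """
    items, thr = default_items()
    cfg = SimulationConfig(
        n=n,
        items=items,
        thresholds=thr,
        factors=[
            FactorSpec("gender", ("Men", "Women"), (0.465, 0.535)),
            FactorSpec("age_band", AGE_BANDS,
                       (0.12, 0.17, 0.18, 0.17, 0.14, 0.12, 0.10)),
            FactorSpec("region", REGIONS,
                       (0.21, 0.10, 0.08, 0.15, 0.07, 0.11, 0.08, 0.09, 0.11)),
            FactorSpec("year", ("1995", "2003"), (0.1386, 0.8614)),
        ],
        quantitative={"ager": dict(zip(AGE_BANDS, [0., 1., 2., 3., 4., 5., 6.]))},
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def write_dataset_csvs(resp: ResponseMatrix, cov: pd.DataFrame,
                       responses_path, covariates_path, seed: int | None = None):
    """Write the two CSV schemas the analysis reads, with a seed header line."""
    header = f"# seed={seed}\n" if seed is not None else ""
    for path, df in ((responses_path, resp.to_dataframe()),
                     (covariates_path, cov)):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)


def read_dataset_csvs(responses_path, covariates_path):
    resp = pd.read_csv(responses_path, comment="#")
    cov = pd.read_csv(covariates_path, comment="#")
    return ResponseMatrix.from_dataframe(resp), cov
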