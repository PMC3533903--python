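"""End-to-end orchestration of the spatio-temporal questionnaire analysis.

Stages: reversal recoding -> super-items -> stage-1 DIF (gender x age x year)
-> stage-2 DIF (region x year, adjusted) -> pseudo-item expansion -> Mokken
checks -> PCM calibration -> item-trait fit test (full and rescaled N) ->
latent regression with backward selection -> explained-variance rate.

Every tabular output is a CSV with a one-line ``#`` metadata header; a JSON
manifest records the seed, thresholds and stage counts so runs are auditable
and reproducible: the pipeline is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import main_effects, pairwise_interactions
from .dif import fit_strata_locations, second_stage_region_year, weighted_anova_dif
from .fit import item_trait_chisq, rescale_statistic
from .mokken import check_mhm_fit, loevinger_coefficients, monotonicity_all
from .questionnaire import (DIFSpec, ItemSpec, ResponseMatrix,
                            build_super_items, expand_pseudo_items,
                            reverse_code)
from .regression import backward_select, calibrate_items, explained_variance_tau

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Analysis thresholds, all defaulting to the survey-analysis values."""

    alpha: float = 0.05               # significance level (DIF and selection)
    dif_location_threshold: float = 0.1
    h_min: float = 0.3
    hj_min: float = 0.3
    hjk_min: float = 0.0
    crit_max: float = 40.0
    fit_n0: int = 500                 # effective sample size for fit rescaling
    n_class_intervals: int = 10
    n_nodes: int = 21
    min_stratum_size: int = 30
    stage1_factors: tuple[str, ...] = ("gender", "age_band", "year")
    region_factor: str = "region"
    year_factor: str = "year"
    ordered_factors: dict = field(default_factory=dict)
    quantitative: tuple[str, ...] = ()    # numeric covariates for regression
    factor_references: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class PipelineResult:
    dif_stage1: pd.DataFrame
    dif_stage2: pd.DataFrame
    mokken: pd.DataFrame
    mokken_pass: bool
    calibration: dict
    fit_full: dict
    fit_rescaled: dict
    regression: pd.DataFrame
    removal_log: list
    tau: float
    counts: dict
    manifest: dict


def _write_csv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    matrix: ResponseMatrix,
    covariates: pd.DataFrame,
    items: list[ItemSpec],
    config: PipelineConfig | None = None,
    super_groups: tuple[tuple[str, ...], ...] = (),
    out_dir: str | Path | None = None,
    resume: bool = False,
    log=print,
) -> PipelineResult:
    """Run the full analysis; optionally write the report bundle to ``out_dir``.

    With ``resume=True`` a stage whose report file already exists under
    ``out_dir`` is recomputed only if its inputs changed upstream (cheap
    stages are always recomputed; the expensive per-stratum fits are cached
    via their CSV).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    meta = f"latentpcm {__version__} seed={cfg.seed} alpha={cfg.alpha}"

    matrix.validate(items)
    matrix = reverse_code(matrix, items)
    if super_groups:
        matrix, items = build_super_items(matrix, items, [list(g) for g in super_groups])
    log(f"[recode] {matrix.n_persons} persons, {matrix.n_items} items")

    # -- stage-1 DIF -------------------------------------------------------
    cache = out / "dif_stage1_locations.csv" if out else None
    if resume and cache is not None and cache.exists():
        cached = pd.read_csv(cache, comment="#")
        factors = list(cfg.stage1_factors)
        loc1 = _locations_from_frame(cached, factors)
    else:
        loc1 = fit_strata_locations(matrix, covariates, list(cfg.stage1_factors),
                                    items, cfg.min_stratum_size)
        if cache is not None:
            _write_csv(loc1.table.assign(n=loc1.sizes).reset_index(), cache, meta)
    rep1 = weighted_anova_dif(loc1, alpha=cfg.alpha,
                              diff_threshold=cfg.dif_location_threshold,
                              ordered_factors=cfg.ordered_factors)
    log(f"[dif-1] {len(loc1.table)} strata; {int(rep1.table['flag'].sum())} flags")

    # -- stage-2 DIF -------------------------------------------------------
    rep2 = second_stage_region_year(
        matrix, covariates, rep1, items,
        region_factor=cfg.region_factor, year_factor=cfg.year_factor,
        alpha=cfg.alpha, diff_threshold=cfg.dif_location_threshold,
        min_stratum_size=cfg.min_stratum_size)
    log(f"[dif-2] {int(rep2.table['flag'].sum())} region/year flags")

    # -- pseudo-item expansion over all retained DIF -----------------------
    splits: dict[str, list] = {}
    for rep in (rep1, rep2):
        for iid, pairs in rep.to_dif_spec().splits.items():
            splits.setdefault(iid, []).extend(pairs)
    expanded, specs = expand_pseudo_items(matrix, covariates, DIFSpec(splits),
                                          items)
    log(f"[pseudo] {len(specs)} items or pseudo-items")

    # -- Mokken checks (on the pre-expansion matrix) -----------------------
    scal = loevinger_coefficients(matrix)
    mono = monotonicity_all(matrix, report=scal)
    passed, reasons = check_mhm_fit(scal, cfg.h_min, cfg.hj_min, cfg.hjk_min,
                                    cfg.crit_max)
    mokken_df = pd.DataFrame([{
        "H": scal.H, "min_Hj": scal.H_j.min(),
        "min_Hjk": np.nanmin(scal.H_jk.to_numpy()
                             [np.triu_indices(matrix.n_items, 1)]),
        "max_crit": mono["crit"].max(), "pass": passed,
        "reasons": "; ".join(reasons)}])
    log(f"[mokken] H={scal.H:.3f} pass={passed}")

    # -- calibration + fit test -------------------------------------------
    bank, sigma2, cal_info = calibrate_items(expanded, specs,
                                             n_nodes=cfg.n_nodes)
    ft = item_trait_chisq(expanded, bank, cfg.n_class_intervals,
                          prior_mean=0.0, prior_var=sigma2)
    sc, sp, note = rescale_statistic(ft.chisq, ft.n, ft.df, cfg.fit_n0)
    log(f"[fit] chisq={ft.chisq:.2f} df={ft.df} rescaled={sc:.2f} p={sp:.3f}")

    # -- latent regression with backward selection -------------------------
    refs = dict(cfg.factor_references) or {
        f: covariates[f].astype(str).iloc[0] for f in cfg.stage1_factors}
    mains = main_effects(covariates, refs, list(cfg.quantitative))
    candidates = mains + pairwise_interactions(mains)
    fitted, removal_log = backward_select(
        expanded, bank, covariates, candidates, list(candidates),
        alpha=cfg.alpha, n_nodes=cfg.n_nodes)
    # tau compares the latent variance without covariates (calibration) with
    # the homoscedastic fit carrying the selected mean terms; parameter counts
    # include the frozen thresholds as in the calibration model
    from .regression import fit_mixed_pcm
    homo = fit_mixed_pcm(expanded, bank, covariates, fitted.mean_effects,
                         [], n_nodes=cfg.n_nodes, compute_se=False)
    k0 = cal_info["k"]
    k_with = k0 + 1 + len(fitted.mean_effects)    # + mu* and mean terms
    tau = explained_variance_tau(sigma2, k0, homo.sigma2_star, k_with,
                                 cal_info["n"])
    log(f"[regress] k={fitted.k} terms={len(fitted.mean_effects)} tau={tau:.3f}")

    counts = {"persons": matrix.n_persons, "items": matrix.n_items,
              "pseudo_items": len(specs), "strata_stage1": len(loc1.table)}
    manifest = {"version": __version__, "seed": cfg.seed,
                "config": {k: v for k, v in asdict(cfg).items()
                           if not isinstance(v, dict)},
                "counts": counts}
    result = PipelineResult(
        rep1.table, rep2.table, mokken_df, passed, cal_info,
        {"chisq": ft.chisq, "df": ft.df, "p": ft.p, "n": ft.n},
        {"chisq": sc, "df": ft.df, "p": sp, "note": note},
        fitted.coef_table(), removal_log, float(tau), counts, manifest)

    if out is not None:
        _write_csv(rep1.table.drop(columns="grouping")
                   .assign(grouping=[_grp(g) for g in rep1.table["grouping"]]),
                   out / "dif_stage1.csv", meta)
        _write_csv(rep2.table.drop(columns="grouping")
                   .assign(grouping=[_grp(g) for g in rep2.table["grouping"]]),
                   out / "dif_stage2.csv", meta)
        _write_csv(mokken_df, out / "mokken.csv", meta)
        _write_csv(result.regression, out / "regression.csv", meta)
        _write_csv(pd.DataFrame(removal_log), out / "removal_log.csv", meta)
        bank.to_csv(out / "item_bank.csv")
        fitdf = pd.DataFrame([result.fit_full | {"scope": "full"},
                              result.fit_rescaled | {"scope": "rescaled", "n": ft.n}])
        _write_csv(fitdf, out / "fit_test.csv", meta)
        manifest["tau"] = float(tau)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return result


def _grp(g):
    return "" if g is None else " | ".join("+".join(x) for x in g)


def _locations_from_frame(df: pd.DataFrame, factors: list[str]):
    from .dif import LocationTable
    df = df.set_index(factors)
    sizes = df.pop("n")
    return LocationTable(df, sizes, factors)
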