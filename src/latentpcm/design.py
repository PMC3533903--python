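"""Design-matrix construction for latent regression.

Effects are products of elementary parts: a level indicator (1 when the
person's factor level belongs to a given set of levels, 0 otherwise) and/or a
quantitative column.  This covers the term shapes used in latent regression of
quality-of-life surveys — treatment-coded factors against a reference group,
grouped-level contrasts such as ``(North, West)``, quantitative recoded age,
and order-2 interactions — while keeping every term individually removable in
backward selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Effect", "indicator", "quant", "interact", "build_design",
           "profile_row", "main_effects", "pairwise_interactions"]


@dataclass(frozen=True)
class _Part:
    kind: str                      # "ind" or "quant"
    name: str                      # factor / column name
    levels: tuple[str, ...] = ()   # for "ind" only


@dataclass(frozen=True)
class Effect:
    """One design column: the product of 1 or 2 elementary parts."""

    parts: tuple[_Part, ...]
    label: str

    @property
    def order(self) -> int:
        return len(self.parts)

    @property
    def variables(self) -> frozenset[str]:
        """Covariate names the effect involves (for selection hierarchy)."""
        return frozenset(p.name for p in self.parts)

    def column(self, covariates: pd.DataFrame) -> np.ndarray:
        col = np.ones(len(covariates))
        for p in self.parts:
            if p.kind == "ind":
                col = col * covariates[p.name].astype(str).isin(p.levels).to_numpy(float)
            else:
                col = col * covariates[p.name].to_numpy(float)
        return col

    def at_profile(self, profile: dict) -> float:
        val = 1.0
        for p in self.parts:
            if p.name not in profile:
                raise ValueError(f"profile lacks covariate {p.name!r}")
            if p.kind == "ind":
                val *= 1.0 if str(profile[p.name]) in p.levels else 0.0
            else:
                val *= float(profile[p.name])
        return val


def indicator(factor: str, *levels: str, label: str | None = None) -> Effect:
    """Indicator of membership in one or several levels of a factor."""
    if not levels:
        raise ValueError("indicator needs at least one level")
    lv = tuple(str(x) for x in levels)
    return Effect((_Part("ind", factor, lv),),
                  label or f"{factor}:" + "+".join(lv))


def quant(column: str, label: str | None = None) -> Effect:
    """Quantitative covariate column used as-is."""
    return Effect((_Part("quant", column),), label or column)


def interact(a: Effect, b: Effect, label: str | None = None) -> Effect:
    parts = a.parts + b.parts
    if len(parts) > 2:
        raise ValueError("only order-2 interactions are supported")
    return Effect(parts, label or f"{a.label}*{b.label}")


def build_design(covariates: pd.DataFrame, effects: list[Effect]) -> np.ndarray:
    """N x P design matrix (no intercept column; the intercept is mu*/sigma2*)."""
    if not effects:
        return np.zeros((len(covariates), 0))
    X = np.column_stack([e.column(covariates) for e in effects])
    return X


def profile_row(effects: list[Effect], profile: dict) -> np.ndarray:
    return np.array([e.at_profile(profile) for e in effects])


def main_effects(covariates: pd.DataFrame, factors: dict[str, str],
                 quantitative: list[str] = ()) -> list[Effect]:
    """Treatment-coded main effects: one indicator per non-reference level.

    ``factors`` maps factor name -> reference level.
    """
    effects: list[Effect] = []
    for f, ref in factors.items():
        for lv in pd.unique(covariates[f].astype(str)):
            if lv != str(ref):
                effects.append(indicator(f, lv, label=f"{f}={lv}"))
    effects += [quant(c) for c in quantitative]
    return effects


def pairwise_interactions(effects: list[Effect]) -> list[Effect]:
    """All order-2 interactions of distinct-variable order-1 effects."""
    out = []
    for i, a in enumerate(effects):
        for b in effects[i + 1:]:
            if a.order == 1 and b.order == 1 and a.variables != b.variables:
                out.append(interact(a, b))
    return out
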