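"""SF-36 dimension definitions and reference estimates from the French
general-population surveys (1995 SOFRES, 2003 INSEE).

Three dimensions are covered: General Health (GH, 5 items on 0-4 after
unweighting item 1 and reversing three items), Physical Functioning (PF, 10
items on 0-2, with three locally dependent sets sum-scored into the
super-items PF12, PF45 and PF789), and Mental Health (MH, 5 items on 0-5).

The module also stores, as plain data, the published latent-regression
estimates for those dimensions — coefficient tables for the mean and variance
of the latent trait, the integer age recodings implied by the fitted age-band
coefficients, the DIF splits retained after the two-stage scan, and the
explained-variance inputs (n, parameter counts, latent variances).  The raw
survey responses are not distributed, so these estimates serve as worked
examples: every derived quantity (profile deviations, explained-variance
rates) is recomputed from them by the package's own functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Effect, indicator, interact, quant
from .questionnaire import DIFSpec, ItemSpec
from .regression import AgeRecoding, LatentRegressionFit

__all__ = [
    "AGE_BANDS", "REGIONS", "YEARS",
    "DimensionSpec", "DIMENSIONS", "published_fit", "published_tau_inputs",
    "published_age_recoding", "published_dif_splits", "reference_profile",
]

AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84")
REGIONS = ("Paris Basin", "North", "East", "Eastern Paris Basin",
           "Western Paris Basin", "West", "South-West", "South-East",
           "Mediterranean Basin")
YEARS = ("1995", "2003")


@dataclass(frozen=True)
class DimensionSpec:
    name: str
    items: tuple[ItemSpec, ...]
    super_groups: tuple[tuple[str, ...], ...] = ()


DIMENSIONS: dict[str, DimensionSpec] = {
    # items 1, 3 and 5 of the dimension are negatively worded and reversed
    "GH": DimensionSpec(
        "General Health",
        tuple(ItemSpec(iid, 5, reverse=rev) for iid, rev in [
            ("GH1", True), ("GH11a", False), ("GH11b", True),
            ("GH11c", False), ("GH11d", True)]),
    ),
    "PF": DimensionSpec(
        "Physical Functioning",
        tuple(ItemSpec(f"PF{i}", 3) for i in range(1, 11)),
        super_groups=(("PF1", "PF2"), ("PF4", "PF5"), ("PF7", "PF8", "PF9")),
    ),
    "MH": DimensionSpec(
        "Mental Health",
        tuple(ItemSpec(f"MH{i}", 6) for i in range(1, 6)),
    ),
}


def reference_profile(**overrides) -> dict:
    """The reference group: men, 18-24 years, Paris Basin, 1995 (ager = 0)."""
    prof = {"gender": "Men", "age_band": "18-24", "region": "Paris Basin",
            "year": "1995", "ager": 0.0}
    prof.update(overrides)
    return prof


# ---------------------------------------------------------------------------
# DIF splits retained after the two-stage scan of the surveys
# ---------------------------------------------------------------------------

_AGE = "age_band"

published_dif_splits: dict[str, DIFSpec] = {
    "GH": DIFSpec({
        "GH1": [(_AGE, [["18-24", "25-34", "35-44"], ["45-54", "55-64"],
                        ["65-74", "75-84"]])],
        "GH11a": [(_AGE, [["18-24", "25-34"], ["35-44", "45-54", "55-64"],
                          ["65-74", "75-84"]])],
    }),
    "PF": DIFSpec({
        "PF3": [("gender", [["Men"], ["Women"]]),
                ("year", [["1995"], ["2003"]])],
        "PF45": [("year", [["1995"], ["2003"]])],
        "PF6": [(_AGE, [["18-24", "25-34"],
                        ["35-44", "45-54", "55-64", "65-74", "75-84"]])],
    }),
    "MH": DIFSpec({
        "MH1": [(_AGE, [["18-24", "25-34", "35-44"], ["45-54"], ["55-64"],
                        ["65-74"], ["75-84"]])],
    }),
}


# ---------------------------------------------------------------------------
# age recodings implied by the fitted age-band coefficients
# ---------------------------------------------------------------------------

published_age_recoding: dict[str, AgeRecoding] = {
    "GH": AgeRecoding(AGE_BANDS, (0., 2., 12., 17., 24., 32., 40.)),
    "PF": AgeRecoding(AGE_BANDS, (0., 1., 2., 4., 6., 8., 10.)),
    # MH used collapsed bands 18-34 / 35-44 / 45-64 / 65-74 / 75-84
    "MH": AgeRecoding(("18-34", "35-44", "45-64", "65-74", "75-84"),
                      (0., 1., 2., 3., 6.)),
}


# ---------------------------------------------------------------------------
# published latent-regression coefficient tables
# ---------------------------------------------------------------------------

def _e(*parts, label=None) -> Effect:
    out = parts[0]
    for p in parts[1:]:
        out = interact(out, p)
    if label:
        out = Effect(out.parts, label)
    return out


_WOMEN = indicator("gender", "Women", label="Women")
_S2003 = indicator("year", "2003", label="Survey 2003")
_AGER = quant("ager", label="Ager")


def _fit(mu_star, beta_terms, sigma2_star, gamma_terms, n, k) -> LatentRegressionFit:
    return LatentRegressionFit(
        mu_star=mu_star,
        sigma2_star=sigma2_star,
        mean_effects=[e for e, _ in beta_terms],
        beta=np.array([b for _, b in beta_terms]),
        var_effects=[e for e, _ in gamma_terms],
        gamma=np.array([g for _, g in gamma_terms]),
        n=n, k=k)


_N_SURVEY = 26388

_PUBLISHED = {
    "GH": _fit(
        0.8238,
        [(_WOMEN, -0.2121),
         (_S2003, -0.1393),
         (_AGER, -0.0349),
         (indicator("region", "East", label="East"), -0.2039),
         (indicator("region", "West", label="West"), 0.1259),
         (indicator("region", "South-West", label="South-West"), -0.0666),
         (_e(_AGER, _WOMEN), 0.0049),
         (_e(_AGER, _S2003), -0.0030),
         (_e(_AGER, indicator("region", "North", "West")), -0.0046),
         (_e(_AGER, indicator("region", "East")), 0.0062),
         (_e(_S2003, indicator("region", "North", "Eastern Paris Basin")), -0.1172),
         (_e(_S2003, indicator("region", "Western Paris Basin", "South-East")),
          -0.0675)],
        1.4130,
        [(_S2003, -0.1499),
         (_AGER, -0.0068),
         (indicator("region", "East", label="East"), -0.2334),
         (indicator("region", "South-West", label="South-West"), -0.1254),
         (_e(_AGER, _S2003), 0.0068)],
        n=_N_SURVEY, k=50),
    "PF": _fit(
        3.1131,
        [(_WOMEN, -1.1154),
         (_S2003, -0.2447),
         (_AGER, -0.5960),
         (indicator("region", "North", label="North"), -0.2809),
         (indicator("region", "Western Paris Basin"), -0.1386),
         (indicator("region", "West", "South-West", "South-East"), 0.3284),
         (_e(_WOMEN, _AGER), 0.0667),
         (_e(_AGER, indicator("region", "North", "Eastern Paris Basin", "West",
                              "South-West", "South-East")), -0.0345)],
        8.9934,
        [(_WOMEN, -2.4176),
         (_S2003, 3.0001),
         (_AGER, -0.5758),
         (_e(_WOMEN, _AGER), 0.1404),
         (_e(_S2003, _AGER), -0.2560)],
        n=_N_SURVEY, k=30),
    "MH": _fit(
        0.5924,
        [(_WOMEN, -0.4654),
         (_S2003, -0.1824),
         (_AGER, -0.0936),
         (indicator("region", "North", "Western Paris Basin"), -0.1650),
         (indicator("region", "East", "Eastern Paris Basin"), -0.0872),
         (indicator("region", "West", "South-West"), 0.1110),
         (_e(_AGER, indicator("region", "North", "West", "South-West")), -0.0425),
         (_e(_WOMEN, indicator("region", "Western Paris Basin")), 0.1421)],
        1.6797,
        [(_AGER, 0.1080),
         (indicator("region", "North", "Eastern Paris Basin",
                    "Western Paris Basin", "South-East"), -0.1349),
         (indicator("region", "East", "West", "South-West"), -0.2305),
         (indicator("region", "Mediterranean Basin"), 0.1549)],
        n=_N_SURVEY, k=54),
}

# explained-variance inputs: (n, k0, sigma0^2, k, sigma^2)
_TAU_INPUTS = {
    "GH": (_N_SURVEY, 37, 1.4272, 50, 1.2406),
    "PF": (_N_SURVEY, 21, 9.3182, 30, 6.8119),
    "MH": (_N_SURVEY, 46, 1.8377, 54, 1.7436),
}


def published_fit(dimension: str) -> LatentRegressionFit:
    """The published latent-regression coefficient table for a dimension."""
    return _PUBLISHED[dimension]


def published_tau_inputs(dimension: str) -> tuple[int, int, float, int, float]:
    """(n, k0, sigma0^2, k, sigma^2) of the published with/without-covariate
    latent-variance comparison."""
    return _TAU_INPUTS[dimension]
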