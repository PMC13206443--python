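"""Nutritional suitability scoring.

Three signals are combined into a composite meal-quality score in [0, 1]:

* **Absolute adequacy** — per-nutrient amount against a per-meal target
  T_m = RDA_m / meals_per_day, capped at 1 so moderate excess is not
  penalized: A_m = min(1, n_m / T_m); A_abs is the mean over the modeled
  nutrient set M.
* **Macronutrient energy balance** — energy shares of protein/carbohydrate/
  fat computed with Atwater factors (4/4/9 kcal per gram), scored by mean
  absolute deviation from target shares (default 30/40/30):
  A_ratio = mean_i (1 - |R_i - R_i_target|).
* **Energy density** — ED = kcal per gram as a satiety proxy; no penalty up
  to a threshold tau, exponential decay beyond it:
  A_ED = 1 if ED <= tau else exp(-kappa (ED - tau)).

Composite: S_nutrition = w1 A_abs + w2 A_ratio + w3 A_ED with
weights (0.5, 0.3, 0.2) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .corpus import NutrientVector, Recipe

ATWATER = {"protein": 4.0, "carbohydrates": 4.0, "fat": 9.0}

#: general-adult daily reference values (kcal for calories, grams otherwise)
DEFAULT_RDA: dict[str, float] = {
    "calories": 2000.0,
    "protein": 50.0,
    "fat": 70.0,
    "carbohydrates": 260.0,
    "fiber": 28.0,
}


class NutritionConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RDATable:
    values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RDA))

    def __post_init__(self):
        for k, v in self.values.items():
            if v <= 0:
                raise NutritionConfigError(f"RDA for {k!r} must be > 0, got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RDATable":
        with open(path, encoding="utf-8") as fh:
            return cls(dict(yaml.safe_load(fh)))


@dataclass(frozen=True)
class NutritionConfig:
    atwater: Mapping[str, float] = field(default_factory=lambda: dict(ATWATER))
    target_ratios: tuple[float, float, float] = (0.30, 0.40, 0.30)  # protein, carb, fat
    tau: float = 1.5        # kcal/g, energy-density penalty threshold
    kappa: float = 1.0      # decay rate of the penalty, per kcal/g
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2)  # A_abs, A_ratio, A_ED
    meals_per_day: int = 3
    modeled_nutrients: tuple[str, ...] = (
        "calories", "protein", "fat", "carbohydrates", "fiber",
    )

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise NutritionConfigError(f"weights must sum to 1, got {self.weights}")
        if abs(sum(self.target_ratios) - 1.0) > 1e-9:
            raise NutritionConfigError(f"target ratios must sum to 1, got {self.target_ratios}")
        if self.tau <= 0 or self.kappa <= 0:
            raise NutritionConfigError("tau and kappa must be > 0")
        if not self.modeled_nutrients:
            raise NutritionConfigError("modeled nutrient set must be non-empty")


def adequacy(n_m: float, rda_m: float, meals_per_day: int = 3) -> float:
    """A_m = min(1, n_m / T_m) with per-meal target T_m = RDA_m / meals."""
    if rda_m <= 0:
        raise NutritionConfigError("RDA must be > 0")
    if n_m < 0:
        raise ValueError(f"negative nutrient amount {n_m}")
    target = rda_m / meals_per_day
    return min(1.0, n_m / target)


def aggregate_adequacy(per_nutrient: Mapping[str, float]) -> float:
    if not per_nutrient:
        raise NutritionConfigError("empty modeled nutrient set")
    return sum(per_nutrient.values()) / len(per_nutrient)


def energy_ratios(
    n: NutrientVector, cfg: NutritionConfig = NutritionConfig()
) -> tuple[float, float, float]:
    """Energy shares (protein, carb, fat) from Atwater-derived energy.

    The denominator is the macro-derived energy, not the stored calories
    field, so the shares always sum to 1 even when the label calories
    disagree with the macros.
    """
    e_prot = cfg.atwater["protein"] * n.protein
    e_carb = cfg.atwater["carbohydrates"] * n.carbohydrates
    e_fat = cfg.atwater["fat"] * n.fat
    total = e_prot + e_carb + e_fat
    if total <= 0:
        raise ValueError("all macronutrients zero; energy ratios undefined")
    return (e_prot / total, e_carb / total, e_fat / total)


def ratio_balance(
    ratios: Sequence[float], cfg: NutritionConfig = NutritionConfig()
) -> float:
    return sum(
        1.0 - abs(r - t) for r, t in zip(ratios, cfg.target_ratios)
    ) / len(cfg.target_ratios)


def energy_density_score(
    calories: float, mass_g: float, cfg: NutritionConfig = NutritionConfig()
) -> tuple[float, float]:
    """Returns (ED, A_ED); continuous at ED = tau."""
    if mass_g <= 0:
        raise ValueError(f"mass must be > 0, got {mass_g}")
    ed = calories / mass_g
    a_ed = 1.0 if ed <= cfg.tau else math.exp(-cfg.kappa * (ed - cfg.tau))
    return ed, a_ed


def composite_score(
    a_abs: float, a_ratio: float, a_ed: float, cfg: NutritionConfig = NutritionConfig()
) -> float:
    w1, w2, w3 = cfg.weights
    return w1 * a_abs + w2 * a_ratio + w3 * a_ed


@dataclass(frozen=True)
class NutritionBreakdown:
    per_nutrient: Mapping[str, float]
    a_abs: float
    ratios: tuple[float, float, float]
    a_ratio: float
    energy_density: float
    a_ed: float
    s_nutrition: float

    def as_dict(self) -> dict:
        return {
            "per_nutrient_adequacy": dict(self.per_nutrient),
            "a_abs": self.a_abs,
            "energy_ratios": {
                "protein": self.ratios[0],
                "carbohydrates": self.ratios[1],
                "fat": self.ratios[2],
            },
            "a_ratio": self.a_ratio,
            "energy_density_kcal_per_g": self.energy_density,
            "a_ed": self.a_ed,
            "s_nutrition": self.s_nutrition,
        }


def score_recipe(
    recipe: Recipe,
    rda: RDATable = RDATable(),
    cfg: NutritionConfig = NutritionConfig(),
) -> NutritionBreakdown:
    """Full nutritional breakdown for one recipe."""
    nut = recipe.nutrients.as_dict()
    per = {
        m: adequacy(nut[m], rda.values[m], cfg.meals_per_day)
        for m in cfg.modeled_nutrients
        if m in nut and m in rda.values
    }
    a_abs = aggregate_adequacy(per)
    try:
        ratios = energy_ratios(recipe.nutrients, cfg)
        a_ratio = ratio_balance(ratios, cfg)
    except ValueError:
        # all-macro-zero edge case: worst balance rather than a crash
        ratios, a_ratio = (0.0, 0.0, 0.0), 0.0
    ed, a_ed = energy_density_score(nut["calories"], recipe.total_mass_g, cfg)
    s = composite_score(a_abs, a_ratio, a_ed, cfg)
    return NutritionBreakdown(per, a_abs, ratios, a_ratio, ed, a_ed, s)
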