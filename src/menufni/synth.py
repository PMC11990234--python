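"""Seeded generator of food-level menu plans, price tables, and egg profiles.

The published food-level menus are not redistributable, so every stage of
the pipeline is exercised against synthetic seven-day plans with the same
structure: ~2000-2400 kcal/day, at least one non-egg protein-group food of
>= 44 g per day, seafood on a configurable number of days, a fraction of
mixed dishes, per-100 g nutrient densities, and a price table with
occasional missing entries.

Densities and prices are drawn log-normally (positive, right-skewed); the
parameters are configuration describing plausible magnitudes, not claims
about real food composition.  A single pseudo-random stream is consumed in
a fixed order (per day: food grams, then group assignments, then densities;
then prices), so a given seed always yields the same plan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    NUTRIENTS,
    DRITable,
    DayMenu,
    EggProfile,
    FoodGroup,
    FoodItem,
    MenuPlan,
    NutrientVector,
    ProteinSubgroup,
    Sex,
)
from .io import PriceTable
from .scoring import plan_daily_totals

#: (median, sigma) of the log-normal density per nutrient, by food group.
#: Units are the nutrient's per-100 g units.
DEFAULT_DENSITY_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "protein": {
        "choline": (70.0, 0.5),
        "potassium": (300.0, 0.3),
        "calcium": (20.0, 0.6),
        "folate": (15.0, 0.6),
        "magnesium": (25.0, 0.4),
        "zinc": (3.0, 0.5),
        "vitamin_d": (0.4, 0.8),
        "vitamin_c": (0.5, 0.8),
        "energy": (180.0, 0.3),
        "protein": (20.0, 0.25),
    },
    "seafood": {
        "choline": (80.0, 0.4),
        "potassium": (350.0, 0.3),
        "calcium": (15.0, 0.6),
        "folate": (10.0, 0.6),
        "magnesium": (30.0, 0.4),
        "zinc": (1.5, 0.5),
        "vitamin_d": (8.0, 0.7),
        "vitamin_c": (0.3, 0.8),
        "energy": (150.0, 0.3),
        "protein": (21.0, 0.25),
    },
    "other": {
        "choline": (15.0, 0.6),
        "potassium": (200.0, 0.5),
        "calcium": (60.0, 0.8),
        "folate": (35.0, 0.8),
        "magnesium": (25.0, 0.5),
        "zinc": (0.8, 0.6),
        "vitamin_d": (0.2, 0.9),
        "vitamin_c": (15.0, 1.0),
        "energy": (120.0, 0.5),
        "protein": (3.0, 0.6),
    },
}

_NON_SEAFOOD_SUBGROUPS = (
    ProteinSubgroup.meat_poultry,
    ProteinSubgroup.legumes_peas_lentils,
    ProteinSubgroup.nuts_seeds_soy,
)


@dataclass(frozen=True)
class SimConfig:
    days: int = 7
    foods_per_day: tuple[int, int] = (6, 12)
    kcal_target: float = 2000.0
    protein_items_per_day: int = 2
    seafood_days: int = 2
    mixed_dish_fraction: float = 0.25
    density_params: dict = field(default_factory=lambda: DEFAULT_DENSITY_PARAMS)
    price_params: tuple[float, float] = (0.45, 0.7)  # USD/100 g (median, sigma)
    #: distinct names per food group; a small protein pool makes the same
    #: protein source recur across days, exercising the variety rule
    protein_name_pool: int = 5
    other_name_pool: int = 25
    missing_price_fraction: float = 0.0
    energy_tolerance: float = 0.15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from a flat YAML mapping of field names to values."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown SimConfig field(s): {sorted(unknown)}")
        for key in ("foods_per_day", "price_params"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def __post_init__(self) -> None:
        if self.foods_per_day[0] > self.foods_per_day[1]:
            raise ValueError("foods_per_day range is inverted")
        if self.protein_items_per_day < 1:
            raise ValueError("need at least one protein item per day")
        if self.foods_per_day[0] < self.protein_items_per_day:
            raise ValueError("foods_per_day lower bound < protein_items_per_day")
        if not 0 <= self.mixed_dish_fraction <= 1:
            raise ValueError("mixed_dish_fraction must be in [0, 1]")
        if not 0 <= self.missing_price_fraction <= 1:
            raise ValueError("missing_price_fraction must be in [0, 1]")
        if self.seafood_days > self.days:
            raise ValueError("seafood_days exceeds days")


def _draw_density(rng: np.random.Generator, params: dict[str, tuple[float, float]]) -> NutrientVector:
    kwargs = {}
    for name in (*NUTRIENTS, "energy", "protein"):
        median, sigma = params[name]
        kwargs[name] = float(median * np.exp(rng.normal(0.0, sigma)))
    return NutrientVector(**kwargs)


def generate_plan(config: SimConfig | None = None, seed: int | None = None) -> MenuPlan:
    """Deterministic synthetic menu plan with the configured structure."""
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    seafood_days = set(
        rng.choice(np.arange(1, config.days + 1), size=config.seafood_days, replace=False)
        .tolist()
    )
    days = []
    for day_idx in range(1, config.days + 1):
        n_foods = int(rng.integers(config.foods_per_day[0], config.foods_per_day[1] + 1))
        foods = []
        for i in range(n_foods):
            is_protein = i < config.protein_items_per_day
            is_seafood = is_protein and i == 0 and day_idx in seafood_days
            if is_seafood:
                group_key = "seafood"
                subgroup = ProteinSubgroup.seafood
            elif is_protein:
                group_key = "protein"
                subgroup = _NON_SEAFOOD_SUBGROUPS[
                    int(rng.integers(0, len(_NON_SEAFOOD_SUBGROUPS)))
                ]
            else:
                group_key = "other"
                subgroup = ProteinSubgroup.none
            grams = (
                float(rng.uniform(60.0, 200.0))
                if is_protein
                else float(rng.uniform(30.0, 250.0))
            )
            mixed = is_protein and bool(rng.random() < config.mixed_dish_fraction)
            pool = config.protein_name_pool if is_protein else config.other_name_pool
            name_idx = int(rng.integers(1, pool + 1))
            density = _draw_density(rng, config.density_params[group_key])
            foods.append(
                FoodItem(
                    food_id=f"d{day_idx}_f{i + 1}",
                    name=f"{group_key} food {name_idx}",
                    grams=grams,
                    density=density,
                    group=FoodGroup.protein if is_protein else FoodGroup.other,
                    protein_subgroup=subgroup,
                    mixed_dish=mixed,
                )
            )
        foods = _calibrate_energy(foods, config)
        days.append(DayMenu(day=day_idx, foods=foods))
    return MenuPlan(name=f"synthetic-{config.seed}", kcal_target=config.kcal_target, days=days)


def _calibrate_energy(foods: list[FoodItem], config: SimConfig) -> list[FoodItem]:
    """Uniformly rescale portions so the day hits the kcal target, then
    restore the >= 44 g floor on protein items (compensating with the
    non-protein portions so the day stays on target)."""

    def day_energy(items: list[FoodItem]) -> float:
        return sum(f.grams * (f.density.energy or 0.0) / 100.0 for f in items)

    energy = day_energy(foods)
    factor = config.kcal_target / energy
    scaled = [dataclasses.replace(f, grams=f.grams * factor) for f in foods]
    bumped = []
    for f in scaled:
        if f.group == FoodGroup.protein and f.grams < 44.0:
            f = dataclasses.replace(f, grams=44.0)
        bumped.append(f)
    # re-balance with the non-protein items if the bump added energy
    residual = config.kcal_target - day_energy(
        [f for f in bumped if f.group == FoodGroup.protein]
    )
    other_energy = day_energy([f for f in bumped if f.group == FoodGroup.other])
    if other_energy > 0 and residual > 0:
        adj = residual / other_energy
        bumped = [
            dataclasses.replace(f, grams=f.grams * adj)
            if f.group == FoodGroup.other
            else f
            for f in bumped
        ]
    return bumped


def generate_price_table(plan: MenuPlan, config: SimConfig | None = None) -> PriceTable:
    """Log-normal prices for a deterministic subset of the plan's foods.

    Exactly ``floor(missing_price_fraction * n_foods)`` food ids are left
    unpriced, chosen from the seeded stream.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 1)  # separate stream from the plan
    food_ids = sorted({f.food_id for d in plan.days for f in d.foods})
    n_missing = int(config.missing_price_fraction * len(food_ids))
    missing = set(
        rng.choice(np.asarray(food_ids, dtype=object), size=n_missing, replace=False)
        .tolist()
        if n_missing
        else []
    )
    median, sigma = config.price_params
    entries = {}
    for fid in food_ids:
        price = float(median * np.exp(rng.normal(0.0, sigma)))
        if fid not in missing:
            entries[fid] = price
    return PriceTable(entries)


def generate_calibrated_plan(
    dri: DRITable, level: float, config: SimConfig | None = None
) -> MenuPlan:
    """Plan whose across-day mean of each nutrient equals ``level`` times
    the sex-averaged DRI — a closed-form target for scoring checks."""
    if level <= 0:
        raise ValueError("level must be > 0")
    plan = generate_plan(config)
    totals = plan_daily_totals(plan)
    means = totals.mean_amounts()
    factors = {}
    for nutrient in NUTRIENTS:
        target = level * (dri.value(nutrient, Sex.female) + dri.value(nutrient, Sex.male)) / 2.0
        # tiny upward guard so a mean meant to sit exactly at the reference
        # is never an ulp under it after the rescale round-trip
        factors[nutrient] = target / means.get(nutrient) * (1.0 + 1e-12)
    new_days = []
    for day in plan.days:
        new_foods = []
        for f in day.foods:
            kwargs = {n: f.density.get(n) * factors[n] for n in NUTRIENTS}
            kwargs["energy"] = f.density.energy
            kwargs["protein"] = f.density.protein
            new_foods.append(dataclasses.replace(f, density=NutrientVector(**kwargs)))
        new_days.append(DayMenu(day=day.day, foods=new_foods))
    return MenuPlan(name=plan.name, kcal_target=plan.kcal_target, days=new_days)


def generate_egg_profile(seed: int = 0, choline_boost: float = 1.0) -> EggProfile:
    """Synthetic egg profile for tests; not real egg composition."""
    rng = np.random.default_rng(seed + 2)
    params = DEFAULT_DENSITY_PARAMS["protein"]
    kwargs = {}
    for name in (*NUTRIENTS, "energy", "protein"):
        median, sigma = params[name]
        kwargs[name] = float(median * np.exp(rng.normal(0.0, sigma)))
    kwargs["choline"] = kwargs["choline"] * choline_boost
    return EggProfile(density=NutrientVector(**kwargs), label="synthetic egg")
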