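"""Partial egg substitution in multi-day menu plans.

One medium egg (44 g) replaces the same gram amount of one protein-source
food per day.  Target selection per day follows three rules, in priority
order:

1. *Eligibility* — the candidate is in the protein food group, is not
   itself an egg, and is served at >= 44 g so the swap is gram-for-gram.
2. *Seafood retention* — a seafood candidate is passed over if removing
   44 g of it would drop the plan's weekly seafood grams below the dietary
   guidance of eight ounce-equivalents per 2000 kcal week (226.8 g, scaled
   linearly with the plan's kcal target).
3. *Variety* — a candidate whose (subgroup, name) was already selected on
   an earlier day ranks below unselected alternatives; within a tier,
   highest absolute protein grams wins, ties broken by menu order.

All operations are pure: the input plan is never mutated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

from .core import (
    DayMenu,
    EggProfile,
    FoodGroup,
    FoodItem,
    MenuPlan,
    NutrientVector,
    ProteinSubgroup,
    scale_to_grams,
)

#: Eight ounce-equivalents of seafood per week, in grams (1 oz = 28.35 g).
SEAFOOD_WEEKLY_TARGET_G = 226.8

DEFAULT_SWAP_GRAMS = 44.0


class Rationale(str, Enum):
    highest_protein = "highest_protein"
    variety_rule_applied = "variety_rule_applied"
    seafood_retained = "seafood_retained"
    no_candidate = "no_candidate"
    skipped = "skipped"


@dataclass(frozen=True)
class SubstitutionRecord:
    day: int
    target_food_id: str | None
    grams_replaced: float
    rationale: Rationale
    delta: NutrientVector

    def __post_init__(self) -> None:
        has_target = self.target_food_id is not None
        if has_target == (self.rationale in (Rationale.no_candidate, Rationale.skipped)):
            raise ValueError("target must be present iff a substitution happened")


@dataclass(frozen=True)
class SelectionRules:
    swap_grams: float = DEFAULT_SWAP_GRAMS
    seafood_weekly_target_g: float = SEAFOOD_WEEKLY_TARGET_G
    reference_kcal: float = 2000.0
    skip_days: frozenset[int] = field(default_factory=frozenset)

    def seafood_floor(self, kcal_target: float) -> float:
        # guidance is stated per 2000 kcal; scale with the plan's energy level
        return self.seafood_weekly_target_g * kcal_target / self.reference_kcal


def identify_protein_candidates(
    day: DayMenu, min_grams: float = DEFAULT_SWAP_GRAMS
) -> list[FoodItem]:
    """Non-egg protein-group foods large enough for a gram-for-gram swap.

    Ordered by descending absolute protein grams in the served portion,
    ties broken by menu order.
    """
    candidates = [
        (i, f)
        for i, f in enumerate(day.foods)
        if f.group == FoodGroup.protein
        and f.protein_subgroup != ProteinSubgroup.eggs
        and f.grams >= min_grams
    ]
    candidates.sort(key=lambda pair: (-pair[1].protein_grams, pair[0]))
    return [f for _, f in candidates]


def _plan_seafood_grams(plan: MenuPlan) -> float:
    return sum(
        f.grams
        for d in plan.days
        for f in d.foods
        if f.protein_subgroup == ProteinSubgroup.seafood
    )


def select_targets(plan: MenuPlan, rules: SelectionRules | None = None) -> list[SubstitutionRecord]:
    """Choose one substitution target per day under the selection rules.

    Returned records carry a zero delta; :func:`substitute_plan` fills in
    the nutrient change when the swap is applied.
    """
    rules = rules or SelectionRules()
    seafood_floor = rules.seafood_floor(plan.kcal_target)
    seafood_remaining = _plan_seafood_grams(plan)
    already_selected: set[tuple[ProteinSubgroup, str]] = set()
    zero = NutrientVector()
    records: list[SubstitutionRecord] = []

    for day in plan.days:
        if day.day in rules.skip_days:
            records.append(
                SubstitutionRecord(day.day, None, 0.0, Rationale.skipped, zero)
            )
            continue
        candidates = identify_protein_candidates(day, rules.swap_grams)
        seafood_blocked = False
        eligible: list[tuple[int, FoodItem]] = []  # (variety_penalty, item)
        for item in candidates:
            if (
                item.protein_subgroup == ProteinSubgroup.seafood
                and seafood_remaining - rules.swap_grams < seafood_floor
            ):
                seafood_blocked = True
                continue
            penalty = int((item.protein_subgroup, item.name) in already_selected)
            eligible.append((penalty, item))
        if not eligible:
            records.append(
                SubstitutionRecord(day.day, None, 0.0, Rationale.no_candidate, zero)
            )
            continue
        # stable: within a penalty tier the protein/menu-order ranking holds
        penalty, chosen = min(eligible, key=lambda pair: pair[0])
        top = candidates[0]
        if chosen is not top and seafood_blocked:
            rationale = Rationale.seafood_retained
        elif chosen is not top:
            rationale = Rationale.variety_rule_applied
        else:
            rationale = Rationale.highest_protein
        if chosen.protein_subgroup == ProteinSubgroup.seafood:
            seafood_remaining -= rules.swap_grams
        already_selected.add((chosen.protein_subgroup, chosen.name))
        records.append(
            SubstitutionRecord(
                day.day, chosen.food_id, rules.swap_grams, rationale, zero
            )
        )
    return records


def apply_substitution(
    day: DayMenu,
    target_food_id: str,
    egg: EggProfile,
    grams: float = DEFAULT_SWAP_GRAMS,
) -> tuple[DayMenu, NutrientVector]:
    """Swap *grams* of the target food for the same grams of egg.

    Returns the new day and the signed nutrient delta
    ``(grams/100) * (egg.density - target.density)``.  Total day grams are
    conserved; the input day is untouched.
    """
    target = next((f for f in day.foods if f.food_id == target_food_id), None)
    if target is None:
        raise KeyError(f"target {target_food_id!r} not found in day {day.day}")
    if target.grams < grams:
        raise ValueError(
            f"target {target_food_id!r} has {target.grams} g < {grams} g to replace"
        )

    new_foods: list[FoodItem] = []
    egg_item_seen = False
    for item in day.foods:
        if item.food_id == target_food_id:
            remaining = item.grams - grams
            if remaining > 0:
                new_foods.append(dataclasses.replace(item, grams=remaining))
        elif (
            not egg_item_seen
            and item.protein_subgroup == ProteinSubgroup.eggs
            and item.name == egg.label
            and item.density == egg.density
        ):
            new_foods.append(dataclasses.replace(item, grams=item.grams + grams))
            egg_item_seen = True
        else:
            new_foods.append(item)
    if not egg_item_seen:
        egg_food = FoodItem(
            food_id=_unique_egg_id(day),
            name=egg.label,
            grams=grams,
            density=egg.density,
            group=FoodGroup.protein,
            protein_subgroup=ProteinSubgroup.eggs,
        )
        new_foods.append(egg_food)
    delta = scale_to_grams(egg.density - target.density, grams)
    return DayMenu(day=day.day, foods=new_foods), delta


def _unique_egg_id(day: DayMenu) -> str:
    base = "egg_boiled"
    existing = {f.food_id for f in day.foods}
    if base not in existing:
        return base
    i = 2
    while f"{base}_{i}" in existing:
        i += 1
    return f"{base}_{i}"


def substitute_plan(
    plan: MenuPlan, egg: EggProfile, rules: SelectionRules | None = None
) -> tuple[MenuPlan, list[SubstitutionRecord]]:
    """Select a target per day and apply the egg swap; days without an
    eligible candidate pass through unchanged."""
    rules = rules or SelectionRules()
    records = select_targets(plan, rules)
    new_days: list[DayMenu] = []
    final_records: list[SubstitutionRecord] = []
    for day, record in zip(plan.days, records):
        if record.target_food_id is None:
            new_days.append(day)
            final_records.append(record)
            continue
        new_day, delta = apply_substitution(
            day, record.target_food_id, egg, record.grams_replaced
        )
        new_days.append(new_day)
        final_records.append(dataclasses.replace(record, delta=delta))
    new_plan = MenuPlan(name=plan.name, kcal_target=plan.kcal_target, days=new_days)
    return new_plan, final_records
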