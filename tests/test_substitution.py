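"""Substitution engine: candidate identification, selection rules, and the
gram-for-gram swap, checked against an exhaustive enumeration oracle."""

import dataclasses

import pytest

from menufni.core import NUTRIENTS, FoodGroup, ProteinSubgroup
from menufni.io import load_egg_profile
from menufni.scoring import plan_daily_totals
from menufni.substitution import (
    Rationale,
    SelectionRules,
    apply_substitution,
    identify_protein_candidates,
    select_targets,
    substitute_plan,
)
from menufni.synth import SimConfig, generate_plan

from conftest import make_food, make_plan


def oracle_select(plan, rules=None):
    """Independent re-derivation of per-day target choice: enumerate every
    candidate, score it as the tuple (variety penalty, -protein grams, menu
    position), apply the seafood floor, and take the lexicographic minimum.
    """
    rules = rules or SelectionRules()
    floor = rules.seafood_weekly_target_g * plan.kcal_target / rules.reference_kcal
    seafood_left = sum(
        f.grams
        for d in plan.days
        for f in d.foods
        if f.protein_subgroup == ProteinSubgroup.seafood
    )
    chosen_names = set()
    picks = []
    for day in plan.days:
        if day.day in rules.skip_days:
            picks.append(None)
            continue
        best_key, best_id = None, None
        for pos, food in enumerate(day.foods):
            if food.group != FoodGroup.protein:
                continue
            if food.protein_subgroup == ProteinSubgroup.eggs:
                continue
            if food.grams < rules.swap_grams:
                continue
            if (
                food.protein_subgroup == ProteinSubgroup.seafood
                and seafood_left - rules.swap_grams < floor
            ):
                continue
            penalty = 1 if (food.protein_subgroup, food.name) in chosen_names else 0
            protein = food.grams * (food.density.protein or 0.0) / 100.0
            key = (penalty, -protein, pos)
            if best_key is None or key < best_key:
                best_key, best_id = key, food.food_id
        picks.append(best_id)
        if best_id is not None:
            food = next(f for f in day.foods if f.food_id == best_id)
            if food.protein_subgroup == ProteinSubgroup.seafood:
                seafood_left -= rules.swap_grams
            chosen_names.add((food.protein_subgroup, food.name))
    return picks


class TestCandidateIdentification:
    def test_ordered_by_absolute_protein_content(self):
        salmon = make_food("salmon", 168.0, protein=22.0, subgroup="seafood")
        beef = make_food("beef", 85.0, protein=26.0, subgroup="meat_poultry")
        day = make_plan([[beef, salmon]]).days[0]
        # 168 g x 22% = 36.96 g beats 85 g x 26% = 22.1 g
        assert [f.food_id for f in identify_protein_candidates(day)] == ["salmon", "beef"]

    def test_eggs_never_candidates(self):
        egg = make_food("egg", 88.0, protein=12.5, subgroup="eggs")
        veg = make_food("broccoli", 150.0, protein=2.8)
        day = make_plan([[egg, veg]]).days[0]
        assert identify_protein_candidates(day) == []

    def test_below_swap_threshold_excluded(self):
        small = make_food("jerky", 30.0, protein=30.0, subgroup="meat_poultry")
        day = make_plan([[small]]).days[0]
        assert identify_protein_candidates(day) == []

    def test_tie_broken_by_menu_order(self):
        a = make_food("a", 100.0, protein=20.0, subgroup="meat_poultry")
        b = make_food("b", 100.0, protein=20.0, subgroup="legumes_peas_lentils")
        day = make_plan([[a, b]]).days[0]
        assert [f.food_id for f in identify_protein_candidates(day)] == ["a", "b"]


class TestSelectionRules:
    def test_seafood_protected_when_weekly_target_binding(self):
        # salmon is the top protein source, but the week holds only 226.8 g
        # of seafood, so removing 44 g would break the weekly target
        salmon = make_food("salmon", 226.8, protein=22.0, subgroup="seafood")
        beef = make_food("roast_beef", 85.0, protein=26.0, subgroup="meat_poultry")
        plan = make_plan([[salmon, beef]])
        records = select_targets(plan)
        assert records[0].target_food_id == "roast_beef"
        assert records[0].rationale == Rationale.seafood_retained

    def test_seafood_eligible_with_surplus(self):
        salmon = make_food("salmon", 400.0, protein=22.0, subgroup="seafood")
        beef = make_food("roast_beef", 85.0, protein=26.0, subgroup="meat_poultry")
        plan = make_plan([[salmon, beef]])
        records = select_targets(plan)
        assert records[0].target_food_id == "salmon"
        assert records[0].rationale == Rationale.highest_protein

    def test_variety_deprioritizes_repeated_source(self):
        steak1 = make_food("steak1", 120.0, protein=25.0, subgroup="meat_poultry", name="Steak-beef")
        steak2 = make_food("steak2", 120.0, protein=25.0, subgroup="meat_poultry", name="Steak-beef")
        lunchmeat = make_food(
            "lunchmeat", 100.0, protein=18.0, subgroup="meat_poultry",
            name="Lunchmeats and sausages, chicken",
        )
        plan = make_plan([[steak1], [steak2, lunchmeat]])
        records = select_targets(plan)
        assert records[0].target_food_id == "steak1"
        assert records[1].target_food_id == "lunchmeat"
        assert records[1].rationale == Rationale.variety_rule_applied

    def test_no_candidate_day(self):
        veg = make_food("broccoli", 150.0, protein=2.8)
        plan = make_plan([[veg]])
        records = select_targets(plan)
        assert records[0].target_food_id is None
        assert records[0].rationale == Rationale.no_candidate

    def test_skip_day_flag(self):
        beef = make_food("beef", 100.0, protein=26.0, subgroup="meat_poultry")
        plan = make_plan([[beef]])
        records = select_targets(plan, SelectionRules(skip_days=frozenset({1})))
        assert records[0].rationale == Rationale.skipped

    @pytest.mark.parametrize("seed", range(40))
    def test_selection_matches_enumeration_oracle(self, seed):
        plan = generate_plan(SimConfig(seed=seed, seafood_days=2, protein_items_per_day=2))
        records = select_targets(plan)
        assert [r.target_food_id for r in records] == oracle_select(plan)


class TestApplySubstitution:
    def test_delta_is_scaled_density_difference(self, simple_egg):
        target = make_food(
            "ham", 100.0, protein=20.0, subgroup="meat_poultry", choline=100.0
        )
        day = make_plan([[target]]).days[0]
        new_day, delta = apply_substitution(day, "ham", simple_egg)
        assert delta.choline == pytest.approx(0.44 * (300.0 - 100.0))
        assert delta.choline == pytest.approx(88.0)

    def test_identical_densities_zero_delta(self, simple_egg):
        target = dataclasses.replace(
            simple_egg.as_food_item("not_egg"),
            protein_subgroup=ProteinSubgroup.meat_poultry,
            grams=100.0,
        )
        day = make_plan([[target]]).days[0]
        _, delta = apply_substitution(day, "not_egg", simple_egg)
        assert all(v == pytest.approx(0.0) for _, v in delta.items())

    def test_target_not_found(self, simple_egg):
        day = make_plan([[make_food("x", 100.0)]]).days[0]
        with pytest.raises(KeyError):
            apply_substitution(day, "missing", simple_egg)

    def test_target_too_small(self, simple_egg):
        target = make_food("tiny", 44.0, protein=20.0, subgroup="meat_poultry")
        day = make_plan([[target, make_food("x", 50.0)]]).days[0]
        with pytest.raises(ValueError, match="tiny"):
            apply_substitution(day, "tiny", simple_egg, grams=50.0)

    def test_exact_grams_removes_target(self, simple_egg):
        target = make_food("tofu", 44.0, protein=10.0, subgroup="nuts_seeds_soy")
        day = make_plan([[target, make_food("rice", 150.0)]]).days[0]
        new_day, _ = apply_substitution(day, "tofu", simple_egg)
        assert "tofu" not in {f.food_id for f in new_day.foods}
        assert new_day.total_grams() == pytest.approx(day.total_grams())

    @pytest.mark.parametrize("seed", range(10))
    def test_gram_conservation(self, seed, simple_egg):
        plan = generate_plan(SimConfig(seed=seed))
        new_plan, records = substitute_plan(plan, simple_egg)
        for before, after in zip(plan.days, new_plan.days):
            total_before = sum(f.grams for f in before.foods)
            total_after = sum(f.grams for f in after.foods)
            assert total_after == pytest.approx(total_before, rel=1e-12)


class TestSubstitutePlan:
    def test_plan_without_candidates_is_unchanged(self, simple_egg):
        plan = make_plan([[make_food("broccoli", 150.0)], [make_food("rice", 200.0)]])
        new_plan, records = substitute_plan(plan, simple_egg)
        assert new_plan == plan
        assert all(r.rationale == Rationale.no_candidate for r in records)

    def test_skip_day_passes_through_identically(self, simple_egg):
        beef = make_food("beef", 100.0, protein=26.0, subgroup="meat_poultry", choline=70.0)
        veg = make_food("kale", 80.0, vitamin_c=40.0)
        plan = make_plan([[beef, veg], [dataclasses.replace(beef, food_id="beef2"), veg]])
        rules = SelectionRules(skip_days=frozenset({2}))
        new_plan, records = substitute_plan(plan, simple_egg, rules)
        # skipped day keeps identical daily totals, mirroring a menu whose
        # as-given and substituted rows coincide
        t0 = plan_daily_totals(plan)
        t1 = plan_daily_totals(new_plan)
        assert t1.day(2) == t0.day(2)
        assert t1.day(1) != t0.day(1)
        assert records[1].rationale == Rationale.skipped

    @pytest.mark.parametrize("seed", range(10))
    def test_output_totals_equal_input_plus_delta(self, seed, simple_egg):
        plan = generate_plan(SimConfig(seed=seed))
        new_plan, records = substitute_plan(plan, simple_egg)
        before = plan_daily_totals(plan)
        after = plan_daily_totals(new_plan)
        for record in records:
            for nutrient in NUTRIENTS:
                expected = before.day(record.day).get(nutrient) + record.delta.get(nutrient)
                assert after.day(record.day).get(nutrient) == pytest.approx(
                    expected, rel=1e-9, abs=1e-9
                )

    def test_inputs_never_mutated_and_deterministic(self, simple_egg):
        plan = generate_plan(SimConfig(seed=5))
        snapshot = generate_plan(SimConfig(seed=5))
        out1 = substitute_plan(plan, simple_egg)
        out2 = substitute_plan(plan, simple_egg)
        assert plan == snapshot
        assert out1 == out2

    @pytest.mark.parametrize("seed", range(10))
    def test_never_targets_an_egg(self, seed, simple_egg):
        plan = generate_plan(SimConfig(seed=seed))
        # seed the plan with an egg item on every day
        plan = dataclasses.replace(
            plan,
            days=tuple(
                dataclasses.replace(
                    d, foods=(*d.foods, simple_egg.as_food_item(f"egg_d{d.day}"))
                )
                for d in plan.days
            ),
        )
        _, records = substitute_plan(plan, simple_egg)
        egg_ids = {f"egg_d{d}" for d in range(1, 8)}
        assert all(r.target_food_id not in egg_ids for r in records)
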