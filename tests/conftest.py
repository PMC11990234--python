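import pytest

from menufni.core import (
    DRIEntry,
    DRITable,
    DayMenu,
    EggProfile,
    FoodGroup,
    FoodItem,
    MenuPlan,
    NutrientVector,
    ProteinSubgroup,
    ReferenceType,
    Sex,
    default_dri_table,
)


def make_food(
    food_id,
    grams,
    protein=None,
    subgroup=None,
    name=None,
    price=None,
    mixed=False,
    **density,
):
    """Terse FoodItem builder: density kwargs are per-100 g components."""
    group = FoodGroup.protein if subgroup else FoodGroup.other
    return FoodItem(
        food_id=food_id,
        name=name or food_id,
        grams=grams,
        density=NutrientVector(protein=protein, **density),
        group=group,
        protein_subgroup=ProteinSubgroup(subgroup) if subgroup else ProteinSubgroup.none,
        mixed_dish=mixed,
        price_per_100g=price,
    )


def make_plan(days_foods, name="test", kcal_target=2000.0):
    days = [DayMenu(day=i + 1, foods=foods) for i, foods in enumerate(days_foods)]
    return MenuPlan(name=name, kcal_target=kcal_target, days=days)


@pytest.fixture(scope="session")
def dri():
    return default_dri_table()


@pytest.fixture(scope="session")
def equal_sex_dri():
    """DRI table whose female and male values coincide for every nutrient."""
    values = {
        "choline": 500.0,
        "potassium": 3000.0,
        "calcium": 1300.0,
        "folate": 400.0,
        "magnesium": 400.0,
        "zinc": 10.0,
        "vitamin_d": 15.0,
        "vitamin_c": 70.0,
    }
    entries = []
    for nutrient, v in values.items():
        for sex in Sex:
            entries.append(DRIEntry(nutrient, sex, ReferenceType.RDA, v))
    return DRITable(entries)


@pytest.fixture
def simple_egg():
    return EggProfile(
        density=NutrientVector(
            choline=300.0,
            potassium=120.0,
            calcium=50.0,
            folate=40.0,
            magnesium=10.0,
            zinc=1.0,
            vitamin_d=2.0,
            vitamin_c=0.0,
            energy=150.0,
            protein=12.5,
        ),
        label="synthetic egg",
    )
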