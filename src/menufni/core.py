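"""Domain model shared by every stage of the menu analysis.

The analysis tracks eight micronutrients that are underconsumed by U.S.
adolescents (14-18 y): choline, potassium, calcium, folate (as dietary
folate equivalents), magnesium, zinc, vitamin D, and vitamin C.  Energy and
protein ride along as optional fields: they are never scored, but protein
drives the substitution target selection and energy is reported.

All food composition is carried as per-100 g densities; per-portion amounts
are always derived with :func:`scale_to_grams`, never stored, so units
cannot drift.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

#: The eight scored micronutrients, in reporting order, with display units.
NUTRIENTS: tuple[str, ...] = (
    "choline",
    "potassium",
    "calcium",
    "folate",
    "magnesium",
    "zinc",
    "vitamin_d",
    "vitamin_c",
)

NUTRIENT_UNITS: dict[str, str] = {
    "choline": "mg",
    "potassium": "mg",
    "calcium": "mg",
    "folate": "mcg DFE",
    "magnesium": "mg",
    "zinc": "mg",
    "vitamin_d": "mcg",
    "vitamin_c": "mg",
}


class Sex(str, Enum):
    female = "female"
    male = "male"


class ReferenceType(str, Enum):
    RDA = "RDA"
    AI = "AI"


class FoodGroup(str, Enum):
    protein = "protein"
    other = "other"


class ProteinSubgroup(str, Enum):
    meat_poultry = "meat_poultry"
    seafood = "seafood"
    eggs = "eggs"
    legumes_peas_lentils = "legumes_peas_lentils"
    nuts_seeds_soy = "nuts_seeds_soy"
    none = "none"


@dataclass(frozen=True)
class NutrientVector:
    """Amounts (or per-100 g densities) of the eight tracked micronutrients.

    Addition and scalar scaling are componentwise; optional energy/protein
    propagate through arithmetic when present on both operands and are
    dropped (None) otherwise.
    """

    choline: float = 0.0
    potassium: float = 0.0
    calcium: float = 0.0
    folate: float = 0.0
    magnesium: float = 0.0
    zinc: float = 0.0
    vitamin_d: float = 0.0
    vitamin_c: float = 0.0
    energy: float | None = None
    protein: float | None = None

    def __post_init__(self) -> None:
        for name in NUTRIENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"nutrient {name!r} must be >= 0")

    def __eq__(self, other: object) -> bool:
        # value equality across the internal unchecked subclass used for deltas
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return all(
            getattr(self, f) == getattr(other, f)
            for f in (*NUTRIENTS, "energy", "protein")
        )

    __hash__ = None  # type: ignore[assignment]

    def get(self, nutrient: str) -> float:
        if nutrient not in NUTRIENTS:
            raise KeyError(nutrient)
        return getattr(self, nutrient)

    def items(self) -> Iterator[tuple[str, float]]:
        for name in NUTRIENTS:
            yield name, getattr(self, name)

    def _combine(self, other: "NutrientVector", sign: float) -> "NutrientVector":
        kwargs = {n: getattr(self, n) + sign * getattr(other, n) for n in NUTRIENTS}
        for opt in ("energy", "protein"):
            a, b = getattr(self, opt), getattr(other, opt)
            kwargs[opt] = a + sign * b if a is not None and b is not None else None
        # differences may be legitimately negative (signed deltas)
        return dataclasses.replace(_UNCHECKED, **kwargs)

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return self._combine(other, +1.0)

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        return self._combine(other, -1.0)

    def scaled(self, factor: float) -> "NutrientVector":
        kwargs = {n: getattr(self, n) * factor for n in NUTRIENTS}
        for opt in ("energy", "protein"):
            v = getattr(self, opt)
            kwargs[opt] = v * factor if v is not None else None
        return dataclasses.replace(_UNCHECKED, **kwargs)

    def as_dict(self, include_optional: bool = False) -> dict[str, float]:
        d = {n: getattr(self, n) for n in NUTRIENTS}
        if include_optional:
            d["energy"] = self.energy
            d["protein"] = self.protein
        return d


class _Unchecked(NutrientVector):
    """Internal prototype that skips the non-negativity check (deltas)."""

    def __post_init__(self) -> None:  # noqa: D401
        pass


_UNCHECKED = _Unchecked()


def signed_vector(**kwargs: float | None) -> NutrientVector:
    """Build a NutrientVector that may hold negative components (a delta)."""
    return dataclasses.replace(_UNCHECKED, **kwargs)


def scale_to_grams(density: NutrientVector, grams: float) -> NutrientVector:
    """Amounts in a *grams* portion of a food with per-100 g *density*."""
    if grams < 0:
        raise ValueError("grams must be >= 0")
    return density.scaled(grams / 100.0)


@dataclass(frozen=True)
class FoodItem:
    food_id: str
    name: str
    grams: float
    density: NutrientVector
    group: FoodGroup = FoodGroup.other
    protein_subgroup: ProteinSubgroup = ProteinSubgroup.none
    mixed_dish: bool = False
    price_per_100g: float | None = None

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValueError(f"grams must be > 0 for {self.food_id!r}")
        is_protein = self.group == FoodGroup.protein
        has_subgroup = self.protein_subgroup != ProteinSubgroup.none
        if is_protein != has_subgroup:
            raise ValueError(
                f"{self.food_id!r}: protein_subgroup must be set iff group is protein"
            )

    @property
    def amounts(self) -> NutrientVector:
        return scale_to_grams(self.density, self.grams)

    @property
    def protein_grams(self) -> float:
        """Absolute grams of protein in the served portion."""
        if self.density.protein is None:
            return 0.0
        return self.grams * self.density.protein / 100.0


@dataclass(frozen=True)
class DayMenu:
    day: int
    foods: tuple[FoodItem, ...]

    def __init__(self, day: int, foods) -> None:
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "foods", tuple(foods))
        if self.day < 1:
            raise ValueError("day index is 1-based")
        if not self.foods:
            raise ValueError("a day needs at least one food")
        ids = [f.food_id for f in self.foods]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate food_id within day {self.day}: {dupes}")

    def totals(self) -> NutrientVector:
        total = self.foods[0].amounts
        for item in self.foods[1:]:
            total = total + item.amounts
        return total

    def total_grams(self) -> float:
        return sum(f.grams for f in self.foods)


@dataclass(frozen=True)
class MenuPlan:
    name: str
    kcal_target: float
    days: tuple[DayMenu, ...]

    def __init__(self, name: str, kcal_target: float, days) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "kcal_target", float(kcal_target))
        object.__setattr__(self, "days", tuple(days))
        if not self.days:
            raise ValueError("plan needs at least one day")
        for i, d in enumerate(self.days, start=1):
            if d.day != i:
                raise ValueError("day indices must run consecutively from 1")


@dataclass(frozen=True)
class DRIEntry:
    nutrient: str
    sex: Sex
    reference_type: ReferenceType
    value: float
    life_stage: str = "14-18 y"

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")
        if self.value <= 0:
            raise ValueError("DRI value must be > 0")


class DRITable:
    """Complete nutrient x sex reference table for one life-stage group.

    Completeness (one entry per nutrient per sex, identical reference type
    across sexes) is enforced at construction so scoring can never run
    against a partial table.
    """

    def __init__(self, entries) -> None:
        self._by_key: dict[tuple[str, Sex], DRIEntry] = {}
        for e in entries:
            key = (e.nutrient, e.sex)
            if key in self._by_key:
                raise ValueError(f"duplicate DRI entry for {key}")
            self._by_key[key] = e
        for n in NUTRIENTS:
            for s in Sex:
                if (n, s) not in self._by_key:
                    raise ValueError(f"DRI table missing entry for ({n}, {s.value})")
            if (
                self._by_key[(n, Sex.female)].reference_type
                != self._by_key[(n, Sex.male)].reference_type
            ):
                raise ValueError(f"reference type differs across sexes for {n}")

    def lookup(self, nutrient: str, sex: Sex | str) -> DRIEntry:
        return self._by_key[(nutrient, Sex(sex))]

    def value(self, nutrient: str, sex: Sex | str) -> float:
        return self.lookup(nutrient, sex).value

    @property
    def entries(self) -> list[DRIEntry]:
        return [self._by_key[(n, s)] for n in NUTRIENTS for s in Sex]

    def __len__(self) -> int:
        return len(self._by_key)


# Adolescent (14-18 y) reference values.  Printed DRI ranges are sex
# dependent; the lower bound of each range belongs to females, the upper to
# males, matching the standard DRI tables.
_DEFAULT_DRI: dict[str, tuple[str, float, float]] = {
    # nutrient: (reference type, female, male)
    "choline": ("AI", 400.0, 550.0),
    "potassium": ("AI", 2300.0, 3000.0),
    "calcium": ("RDA", 1300.0, 1300.0),
    "folate": ("RDA", 400.0, 400.0),
    "magnesium": ("AI", 360.0, 410.0),
    "zinc": ("RDA", 9.0, 11.0),
    "vitamin_d": ("RDA", 15.0, 15.0),
    "vitamin_c": ("RDA", 65.0, 75.0),
}


def default_dri_table() -> DRITable:
    """Built-in DRI table for adolescents 14-18 years (RDA or AI per sex)."""
    entries = []
    for nutrient, (ref, female, male) in _DEFAULT_DRI.items():
        rt = ReferenceType(ref)
        entries.append(DRIEntry(nutrient, Sex.female, rt, female))
        entries.append(DRIEntry(nutrient, Sex.male, rt, male))
    return DRITable(entries)


@dataclass(frozen=True)
class EggProfile:
    """The substituted egg: a 44 g medium boiled egg by default."""

    density: NutrientVector
    grams: float = 44.0
    label: str = "Egg, boiled (hard or soft)"
    source_code: str = "NDSR 975"

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValueError("egg grams must be > 0")

    def as_food_item(self, food_id: str = "egg_boiled") -> FoodItem:
        return FoodItem(
            food_id=food_id,
            name=self.label,
            grams=self.grams,
            density=self.density,
            group=FoodGroup.protein,
            protein_subgroup=ProteinSubgroup.eggs,
        )
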