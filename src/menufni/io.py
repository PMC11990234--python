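"""Readers and writers for menu plans, nutrient-totals tables, price tables,
and the packaged transcriptions of the published daily totals and prices.

Menu plans travel as long-format CSV: one row per (day, food), with wide
per-100 g nutrient density columns.  Daily-totals tables mirror the printed
nutrient table (menu, condition, day, eight nutrient columns); price tables
are two columns (food_id, price_usd_per_100g).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    NUTRIENTS,
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
)

logger = logging.getLogger(__name__)

MENU_NAMES = ("HUSS", "DASH", "Harvard", "HVEG")
CONDITIONS = ("as_given", "egg_substitution")

#: CSV column holding each nutrient's daily total, in fixture files.
_TOTAL_COLS = {
    "choline": "choline_mg",
    "potassium": "potassium_mg",
    "calcium": "calcium_mg",
    "folate": "folate_mcg",
    "magnesium": "magnesium_mg",
    "zinc": "zinc_mg",
    "vitamin_d": "vitamin_d_mcg",
    "vitamin_c": "vitamin_c_mg",
}

_DENSITY_COLS = {n: f"{col}_per_100g" for n, col in _TOTAL_COLS.items()}

_MENU_PLAN_COLUMNS = [
    "menu",
    "day",
    "food_id",
    "name",
    "grams",
    "group",
    "protein_subgroup",
    "mixed_dish",
    "price_per_100g",
    "energy_kcal_per_100g",
    "protein_g_per_100g",
    *_DENSITY_COLS.values(),
]


class MenuFormatError(ValueError):
    """A menu/totals/price file does not match the expected layout."""


@dataclass(frozen=True)
class TotalsTable:
    """Daily nutrient totals for one menu under one condition."""

    menu_name: str
    condition: str
    rows: Mapping[int, NutrientVector]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("totals table needs at least one day")

    @property
    def days(self) -> list[int]:
        return sorted(self.rows)

    def day(self, day: int) -> NutrientVector:
        return self.rows[day]

    def daily_amounts(self, nutrient: str) -> list[float]:
        return [self.rows[d].get(nutrient) for d in self.days]

    def mean_amounts(self) -> NutrientVector:
        n = len(self.rows)
        kwargs = {
            nut: sum(v.get(nut) for v in self.rows.values()) / n for nut in NUTRIENTS
        }
        return NutrientVector(**kwargs)


class PriceTable:
    """Food-level as-consumed prices, USD per 100 g."""

    def __init__(self, entries: Mapping[str, float] | None = None) -> None:
        self._entries: dict[str, float] = {}
        for food_id, price in (entries or {}).items():
            if price < 0:
                raise ValueError(f"negative price for {food_id!r}")
            self._entries[food_id] = float(price)

    def get(self, food_id: str) -> float | None:
        return self._entries.get(food_id)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> dict[str, float]:
        return dict(self._entries)


# ---------------------------------------------------------------------------
# menu plan CSV

def _food_from_row(row: pd.Series, context: str) -> FoodItem:
    try:
        grams = float(row["grams"])
    except (TypeError, ValueError):
        raise MenuFormatError(f"{context}: non-numeric grams {row['grams']!r}")
    density_kwargs = {}
    for nutrient, col in _DENSITY_COLS.items():
        density_kwargs[nutrient] = float(row[col]) if pd.notna(row[col]) else 0.0
    for opt, col in (("energy", "energy_kcal_per_100g"), ("protein", "protein_g_per_100g")):
        density_kwargs[opt] = float(row[col]) if pd.notna(row.get(col)) else None
    price = row.get("price_per_100g")
    return FoodItem(
        food_id=str(row["food_id"]),
        name=str(row["name"]),
        grams=grams,
        density=NutrientVector(**density_kwargs),
        group=FoodGroup(str(row["group"])),
        protein_subgroup=ProteinSubgroup(str(row["protein_subgroup"])),
        mixed_dish=bool(row["mixed_dish"]) if pd.notna(row.get("mixed_dish")) else False,
        price_per_100g=float(price) if pd.notna(price) else None,
    )


def read_menu_plan(path: str | Path, kcal_target: float | None = None) -> MenuPlan:
    """Read a long-format menu plan CSV into a validated :class:`MenuPlan`.

    Unknown columns are ignored with a logged warning; missing required
    columns raise :class:`MenuFormatError` naming the column.
    """
    # round_trip float parsing keeps write->read bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"menu", "day", "food_id", "name", "grams", "group", "protein_subgroup"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise MenuFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in _MENU_PLAN_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    extra = set(df.columns) - set(_MENU_PLAN_COLUMNS)
    if extra:
        logger.warning("ignoring unknown menu columns: %s", sorted(extra))

    name = str(df["menu"].iloc[0])
    days = []
    for day_idx, day_df in df.groupby("day", sort=True):
        foods = [
            _food_from_row(row, f"day {day_idx}, row {i}")
            for i, (_, row) in enumerate(day_df.iterrows())
        ]
        days.append(DayMenu(day=int(day_idx), foods=foods))
    if kcal_target is None:
        kcal_target = 2000.0
    return MenuPlan(name=name, kcal_target=kcal_target, days=days)


def write_menu_plan(plan: MenuPlan, path: str | Path) -> None:
    rows = []
    for day in plan.days:
        for item in day.foods:
            row = {
                "menu": plan.name,
                "day": day.day,
                "food_id": item.food_id,
                "name": item.name,
                "grams": item.grams,
                "group": item.group.value,
                "protein_subgroup": item.protein_subgroup.value,
                "mixed_dish": item.mixed_dish,
                "price_per_100g": item.price_per_100g,
                "energy_kcal_per_100g": item.density.energy,
                "protein_g_per_100g": item.density.protein,
            }
            for nutrient, col in _DENSITY_COLS.items():
                row[col] = item.density.get(nutrient)
            rows.append(row)
    # %.17g guarantees bit-exact float round-trips through the CSV
    pd.DataFrame(rows, columns=_MENU_PLAN_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# totals / price tables

def _totals_from_df(df: pd.DataFrame, menu_name: str, condition: str) -> TotalsTable:
    rows = {}
    for _, row in df.iterrows():
        kwargs = {nut: float(row[col]) for nut, col in _TOTAL_COLS.items()}
        rows[int(row["day"])] = NutrientVector(**kwargs)
    return TotalsTable(menu_name=menu_name, condition=condition, rows=rows)


def read_totals_csv(path: str | Path, menu_name: str, condition: str) -> TotalsTable:
    df = pd.read_csv(path)
    missing = sorted((set(_TOTAL_COLS.values()) | {"day"}) - set(df.columns))
    if missing:
        raise MenuFormatError(f"missing required column(s): {', '.join(missing)}")
    if "menu" in df.columns:
        df = df[(df["menu"] == menu_name) & (df["condition"] == condition)]
    return _totals_from_df(df, menu_name, condition)


def write_totals_csv(tables: list[TotalsTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for day in t.days:
            row = {"menu": t.menu_name, "condition": t.condition, "day": day}
            for nut, col in _TOTAL_COLS.items():
                row[col] = t.rows[day].get(nut)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_price_table(path: str | Path) -> PriceTable:
    df = pd.read_csv(path)
    for col in ("food_id", "price_usd_per_100g"):
        if col not in df.columns:
            raise MenuFormatError(f"missing required column(s): {col}")
    return PriceTable(dict(zip(df["food_id"].astype(str), df["price_usd_per_100g"])))


def write_price_table(prices: PriceTable, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(prices.entries.items()), columns=["food_id", "price_usd_per_100g"]
    )
    df.to_csv(path, index=False)


def read_similarity_map(path: str | Path) -> dict[str, str]:
    """Two-column mapping food_id -> substitute_food_id for unpriced items."""
    df = pd.read_csv(path)
    for col in ("food_id", "substitute_food_id"):
        if col not in df.columns:
            raise MenuFormatError(f"missing required column(s): {col}")
    return dict(zip(df["food_id"].astype(str), df["substitute_food_id"].astype(str)))


# ---------------------------------------------------------------------------
# packaged fixtures (published daily totals, daily means, daily prices)

def _data_path(name: str):
    return resources.files("menufni.data").joinpath(name)


def _check_menu(menu_name: str) -> None:
    if menu_name not in MENU_NAMES:
        raise KeyError(f"unknown menu {menu_name!r}; expected one of {MENU_NAMES}")


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def load_fixture_totals(menu_name: str, condition: str) -> TotalsTable:
    """Daily nutrient totals exactly as printed for one menu and condition."""
    _check_menu(menu_name)
    _check_condition(condition)
    with resources.as_file(_data_path("menu_daily_totals.csv")) as p:
        df = pd.read_csv(p)
    sub = df[(df["menu"] == menu_name) & (df["condition"] == condition)]
    return _totals_from_df(sub, menu_name, condition)


def load_fixture_printed_means(menu_name: str, condition: str) -> NutrientVector:
    """The printed 'Daily mean' row for one menu and condition."""
    _check_menu(menu_name)
    _check_condition(condition)
    with resources.as_file(_data_path("menu_daily_means.csv")) as p:
        df = pd.read_csv(p)
    row = df[(df["menu"] == menu_name) & (df["condition"] == condition)].iloc[0]
    return NutrientVector(**{nut: float(row[col]) for nut, col in _TOTAL_COLS.items()})


def load_fixture_prices(menu_name: str) -> dict[str, list[float]]:
    """Printed daily menu prices (USD), 7 per condition, for one menu."""
    _check_menu(menu_name)
    with resources.as_file(_data_path("menu_daily_prices.csv")) as p:
        df = pd.read_csv(p)
    out = {}
    for condition in CONDITIONS:
        sub = df[(df["menu"] == menu_name) & (df["condition"] == condition)]
        out[condition] = [float(v) for v in sub.sort_values("day")["price_usd"]]
    return out


def load_dri_table(path: str | Path | None = None) -> DRITable:
    """DRI table from CSV; defaults to the packaged adolescent 14-18 y table."""
    if path is None:
        with resources.as_file(_data_path("dri_adolescent_14_18.csv")) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    entries = [
        DRIEntry(
            nutrient=str(row["nutrient"]),
            sex=Sex(str(row["sex"])),
            reference_type=ReferenceType(str(row["reference_type"])),
            value=float(row["value"]),
            life_stage=str(row.get("life_stage", "14-18 y")),
        )
        for _, row in df.iterrows()
    ]
    return DRITable(entries)


def load_egg_profile(path: str | Path | None = None) -> EggProfile:
    """Egg profile from JSON; defaults to the packaged boiled-egg profile.

    The packaged default carries generic whole-egg composition reference
    densities; swap in your own profile for exact replication work.
    """
    if path is None:
        raw = _data_path("egg_boiled.json").read_text()
    else:
        raw = Path(path).read_text()
    obj = json.loads(raw)
    density = NutrientVector(**obj["density_per_100g"])
    return EggProfile(
        density=density,
        grams=float(obj.get("grams", 44.0)),
        label=str(obj.get("label", "Egg, boiled (hard or soft)")),
        source_code=str(obj.get("source_code", "NDSR 975")),
    )


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of each packaged fixture file (guards transcription edits)."""
    import hashlib

    out = {}
    for name in (
        "menu_daily_totals.csv",
        "menu_daily_means.csv",
        "menu_daily_prices.csv",
        "dri_adolescent_14_18.csv",
    ):
        out[name] = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
    return out
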