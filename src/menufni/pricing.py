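"""Daily and mean menu cost from an as-consumed USD/100 g price table.

Pricing is linear: a food's cost is grams/100 times its price per 100 g.
Unpriced foods are handled by policy — ``skip_and_log`` omits them and
records the omission (how small unmatched spices were handled in the source
price database), ``map_then_skip`` first consults a user-supplied
similarity mapping, ``error`` aborts on the first unpriced item.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .core import DayMenu, MenuPlan
from .io import PriceTable, load_fixture_prices, MENU_NAMES, CONDITIONS


class MissingPolicy(str, Enum):
    skip_and_log = "skip_and_log"
    map_then_skip = "map_then_skip"
    error = "error"


class UnpricedFoodError(KeyError):
    pass


@dataclass(frozen=True)
class PriceResult:
    daily: dict[int, float]  # day -> USD
    mean: float
    sd: float  # sample (n-1)
    missing_items: list[tuple[int, str, str]]  # (day, food_id, policy note)


def _resolve_price(
    food_id: str,
    item_price: float | None,
    prices: PriceTable,
    policy: MissingPolicy,
    mapping: Mapping[str, str] | None,
) -> tuple[float | None, str | None]:
    """Return (price, note). note is set when a policy was applied."""
    price = prices.get(food_id)
    if price is None and item_price is not None:
        price = item_price
    if price is not None:
        return price, None
    if policy == MissingPolicy.map_then_skip and mapping and food_id in mapping:
        mapped = prices.get(mapping[food_id])
        if mapped is not None:
            return mapped, f"mapped_to:{mapping[food_id]}"
        return None, f"mapped_to_unpriced:{mapping[food_id]}"
    if policy == MissingPolicy.error:
        raise UnpricedFoodError(f"no price for food {food_id!r}")
    return None, "skipped"


def price_day(
    day: DayMenu,
    prices: PriceTable,
    policy: MissingPolicy = MissingPolicy.skip_and_log,
    mapping: Mapping[str, str] | None = None,
) -> tuple[float, list[tuple[int, str, str]]]:
    """Total USD for one day; returns (total, omissions)."""
    total = 0.0
    missing: list[tuple[int, str, str]] = []
    for item in day.foods:
        price, note = _resolve_price(
            item.food_id, item.price_per_100g, prices, MissingPolicy(policy), mapping
        )
        if price is None:
            missing.append((day.day, item.food_id, note or "skipped"))
            continue
        total += item.grams / 100.0 * price
    return total, missing


def price_plan(
    plan: MenuPlan,
    prices: PriceTable,
    policy: MissingPolicy = MissingPolicy.skip_and_log,
    mapping: Mapping[str, str] | None = None,
) -> PriceResult:
    daily: dict[int, float] = {}
    missing: list[tuple[int, str, str]] = []
    for day in plan.days:
        total, day_missing = price_day(day, prices, policy, mapping)
        daily[day.day] = total
        missing.extend(day_missing)
    return summarize_daily_prices(daily, missing)


def summarize_daily_prices(
    daily: Mapping[int, float], missing: list[tuple[int, str, str]] | None = None
) -> PriceResult:
    values = [daily[d] for d in sorted(daily)]
    mean = sum(values) / len(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return PriceResult(daily=dict(daily), mean=mean, sd=sd, missing_items=missing or [])


def summarize_price_fixtures() -> dict[tuple[str, str], tuple[float, float]]:
    """(mean, sample SD) recomputed from the printed daily prices for all
    eight menu-condition pairs."""
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for menu in MENU_NAMES:
        fixture = load_fixture_prices(menu)
        for condition in CONDITIONS:
            values = fixture[condition]
            mean = sum(values) / len(values)
            sd = statistics.stdev(values)
            out[(menu, condition)] = (mean, sd)
    return out
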