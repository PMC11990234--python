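"""Food Nutrient Index (FNI) scoring.

Each of the eight tracked micronutrients contributes a component score: the
percent of the sex-specific RDA or AI supplied by the menu, capped at 100
per sex *before* averaging the two sexes.  The total FNI is the equal-weight
arithmetic mean of the eight components.  Two aggregation modes are offered:

``mean_of_days``
    Average the daily amounts across the menu cycle first, then score the
    means (the published construction).
``per_day``
    Score each day separately, yielding a daily FNI series with a mean and
    sample SD; useful for attaching dispersion and paired tests to totals.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .core import NUTRIENTS, DRITable, MenuPlan, NutrientVector, Sex, scale_to_grams
from .io import TotalsTable

MEAN_OF_DAYS = "mean_of_days"
PER_DAY = "per_day"


@dataclass(frozen=True)
class FNIResult:
    mode: str
    component_by_sex: dict[str, dict[str, float]]  # nutrient -> sex -> score
    component: dict[str, float]  # nutrient -> sex-averaged score
    total: float
    daily_totals: dict[int, float] | None = None
    daily_sd: float | None = None

    def rounded_components(self) -> dict[str, float]:
        """Components rounded half-even to 1 decimal for display."""
        return {n: _round1(s) for n, s in self.component.items()}

    @property
    def total_rounded(self) -> float:
        return _round1(self.total)


def _round1(x: float) -> float:
    # round-half-even at 1 decimal, as values are displayed
    return float(round(x, 1))


def component_score(amount: float, dri_female: float, dri_male: float) -> float:
    """Sex-averaged capped percent-of-DRI score for one nutrient amount.

    The 100-point cap applies per sex before the two sexes are averaged:
    a menu above the female reference but below the male one earns
    (100 + 100*amount/dri_male) / 2, not a capped average.
    """
    if dri_female <= 0 or dri_male <= 0:
        raise ValueError("DRI values must be > 0")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    # ratio first: an amount exactly at (or above) its reference then caps
    # at exactly 100 regardless of float rounding
    scores = [min(100.0, 100.0 * (amount / dri)) for dri in (dri_female, dri_male)]
    return sum(scores) / 2.0


def _score_vector(amounts: NutrientVector, dri: DRITable):
    by_sex: dict[str, dict[str, float]] = {}
    averaged: dict[str, float] = {}
    for nutrient in NUTRIENTS:
        amount = amounts.get(nutrient)
        f = dri.value(nutrient, Sex.female)
        m = dri.value(nutrient, Sex.male)
        by_sex[nutrient] = {
            "female": min(100.0, 100.0 * (amount / f)),
            "male": min(100.0, 100.0 * (amount / m)),
        }
        averaged[nutrient] = component_score(amount, f, m)
    total = sum(averaged.values()) / len(averaged)
    return by_sex, averaged, total


def score_totals_mean_mode(totals: TotalsTable, dri: DRITable) -> FNIResult:
    """FNI from across-day mean amounts (score-of-mean construction)."""
    by_sex, averaged, total = _score_vector(totals.mean_amounts(), dri)
    return FNIResult(
        mode=MEAN_OF_DAYS, component_by_sex=by_sex, component=averaged, total=total
    )


def score_totals_per_day_mode(totals: TotalsTable, dri: DRITable) -> FNIResult:
    """Daily FNI series: score each day, report mean and sample SD of totals.

    Components reported are the across-day means of the daily components.
    """
    daily_totals: dict[int, float] = {}
    comp_accum: dict[str, float] = {n: 0.0 for n in NUTRIENTS}
    sex_accum: dict[str, dict[str, float]] = {
        n: {"female": 0.0, "male": 0.0} for n in NUTRIENTS
    }
    days = totals.days
    for day in days:
        by_sex, averaged, day_total = _score_vector(totals.day(day), dri)
        daily_totals[day] = day_total
        for n in NUTRIENTS:
            comp_accum[n] += averaged[n]
            for sex in ("female", "male"):
                sex_accum[n][sex] += by_sex[n][sex]
    n_days = len(days)
    component = {n: v / n_days for n, v in comp_accum.items()}
    component_by_sex = {
        n: {sex: v / n_days for sex, v in d.items()} for n, d in sex_accum.items()
    }
    values = [daily_totals[d] for d in days]
    mean_total = sum(values) / n_days
    sd = statistics.stdev(values) if n_days > 1 else 0.0
    return FNIResult(
        mode=PER_DAY,
        component_by_sex=component_by_sex,
        component=component,
        total=mean_total,
        daily_totals=daily_totals,
        daily_sd=sd,
    )


def plan_daily_totals(plan: MenuPlan) -> TotalsTable:
    """Sum per-portion nutrient amounts over each day's foods."""
    rows = {}
    for day in plan.days:
        total = scale_to_grams(day.foods[0].density, day.foods[0].grams)
        for item in day.foods[1:]:
            total = total + scale_to_grams(item.density, item.grams)
        rows[day.day] = total
    return TotalsTable(menu_name=plan.name, condition="computed", rows=rows)
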