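# menufni

Modeling the substitution of one egg for another protein-source food in
multi-day exemplary menus, with application to U.S. adolescents (14–18 y).

Exemplary menus — the seven-day Healthy U.S.-Style pattern (HUSS), the DASH
diet menu, the Harvard Healthy Eating Guide menu, and the Healthy
Vegetarian U.S.-Style pattern (HVEG) — operationalize high-quality diets,
yet adolescents' intakes of several micronutrients (notably choline and
vitamin D) fall short of reference values. This package models a practical
tweak: each day, 44 g of one protein-source food (one medium boiled egg's
worth) is swapped gram-for-gram for an egg, and the package quantifies what
that does to micronutrient quality and daily menu cost. It is aimed at
nutrition researchers and menu planners who want a reproducible pipeline for
this class of substitution analysis.

## The model

**Food Nutrient Index (FNI).** For each of eight underconsumed
micronutrients (choline, potassium, calcium, folate as DFE, magnesium,
zinc, vitamin D, vitamin C), the component score for a daily amount *x* is
the capped percent of the sex-specific RDA or AI:

```
score_s(x) = min(100, 100 · x / DRI_s),   s ∈ {female, male}
component(x) = ( score_F(x) + score_M(x) ) / 2
FNI = (1/8) Σ components
```

The cap applies per sex *before* averaging; only this order reproduces the
published score table when one sex sits above its reference and the other
below. Amounts are the across-day means of daily menu totals (score-of-mean
mode); a per-day mode that scores each day separately is also provided for
dispersion and paired testing.

**Substitution rule.** Per day, the eligible candidates are the non-egg
protein-group foods served at ≥ 44 g. The highest-protein candidate (grams
of protein in the served portion) is chosen, except that (a) a seafood item
is retained if removing 44 g would drop the week below the eight
ounce-equivalent seafood guidance (226.8 g per 2000 kcal week), and (b) a
protein source already used on an earlier day is deprioritized for variety.
The swap conserves total grams; the daily nutrient change is
`0.44 · (egg density − target density)` per 100 g densities.

**Cost.** Daily menu price is `Σ grams/100 × price`, from an as-consumed
USD/100 g price table, with explicit policies for unpriced items
(skip-and-log, similarity mapping, or error). Conditions are compared with
two-sided t-tests at Bonferroni-adjusted thresholds (0.05/256 for the
per-nutrient family, 0.05/4 for FNI totals and prices).

## Worked example

```python
from menufni import default_dri_table, load_fixture_totals
from menufni.scoring import component_score, score_totals_mean_mode

# the worked component example: 624 mg calcium vs the 1300 mg RDA
print(component_score(624, 1300, 1300))   # 48.0

dri = default_dri_table()
for condition in ("as_given", "egg_substitution"):
    r = score_totals_mean_mode(load_fixture_totals("HUSS", condition), dri)
    print(condition, round(r.component["choline"], 1),
          round(r.component["vitamin_d"], 1), round(r.total, 1))
```

prints

```
48.0
as_given 83.5 69.2 94.1
egg_substitution 95.2 75.2 96.3
```

i.e. substituting one egg per day raises the HUSS menu's choline component
from 83.5 to 95.2 and vitamin D from 69.2 to 75.2, lifting the total FNI
from 94.1 to 96.3 — while the mean daily price (see
`analysis/03_price_menus.py`) edges down from USD 9.61 to USD 9.51.

## Analysis scripts

The numbered drivers under `analysis/` run each stage on the packaged
fixtures and write tables under `results/`:

1. `01_check_nutrient_tables.py` — recomputed vs printed daily-mean nutrients
2. `02_score_fni.py` — FNI components and totals, both conditions
3. `03_price_menus.py` — daily-price means and SDs
4. `04_compare_conditions.py` — the three Bonferroni-adjusted test families
5. `05_simulate_substitution.py` — the substitution engine on 100 seeded
   synthetic plans

A `menufni` CLI exposes the same stages (`menufni reproduce`, `substitute`,
`score`, `price`, `compare`, `simulate`, `pipeline`) for user-supplied menu
CSVs.

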