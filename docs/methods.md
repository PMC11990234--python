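# Methods

## Scope and data

The pipeline operates on three kinds of input: food-level menu plans (one
row per day per food, grams as consumed, per-100 g nutrient densities),
daily nutrient-totals tables, and as-consumed price tables (USD per 100 g).
The package ships transcriptions of the published daily nutrient totals
(4 menus × 7 days × 2 conditions × 8 nutrients) and daily prices for the
HUSS, DASH, Harvard, and HVEG exemplary menus; these fixtures are guarded by
SHA-256 checksums in the test suite and are the anchor for every
reproduction check. The food-level composition of those menus was never
published, so food-level behaviour is validated on synthetic plans instead
(see below).

## DRI registry

The built-in reference table covers adolescents 14–18 y: choline AI 400/550
mg, potassium AI 2300/3000 mg, magnesium AI 360/410 mg, zinc RDA 9/11 mg,
vitamin C RDA 65/75 mg (female/male), calcium RDA 1300 mg, folate RDA 400
mcg DFE, vitamin D RDA 15 mcg (both sexes). The lower bound of each
sex-dependent range is assigned to females and the upper to males, matching
standard DRI tables; this assignment is confirmed by the score table it
reproduces. Tables for other life stages can be supplied as CSV
(`nutrient,sex,reference_type,value,unit,life_stage`); completeness (8
nutrients × 2 sexes, one reference type per nutrient) is enforced at
construction so scoring can never run against a partial table.

## FNI scoring

Component scores are `min(100, 100·x/DRI_s)` per sex, then averaged over
sexes; the total is the unweighted mean of the eight components.

Two deliberate numerical choices:

- **Cap before averaging.** The two orders differ whenever one sex is above
  its reference and the other below (e.g. 9.67 mg zinc against 9/11 mg:
  cap-first gives 93.95, average-first 97.65); only cap-first reproduces
  the published components.
- **Ratio before scaling.** Scores are computed as `100·(x/DRI)`, not
  `100·x/DRI`, so an amount exactly at its reference caps at exactly 100
  regardless of float rounding.

Aggregation modes: `mean_of_days` averages daily amounts across the cycle
first and scores the means — this is the published construction and the one
used for all reproduction checks. `per_day` scores each day and reports the
daily series with its mean and sample SD; it exists to attach dispersion
and paired tests to the total score. The published total-score SDs
(e.g. 94.0 ± 2.3) and the four score p-values could not be reconstructed
from any per-day construction derivable from the printed dailies, so they
are reported from `per_day` mode but never asserted against the printed
values.

Scores are carried at full precision and rounded half-even to 1 decimal for
display. Reproduction checks use ±0.2 because the printed inputs are
themselves rounded to 1 dp (e.g. the Harvard vitamin D component recomputes
to 65.24 against a printed 65.1).

## Substitution engine

Per day, candidates are protein-group foods, excluding eggs themselves,
served at ≥ 44 g — the swap is always gram-for-gram with one 44 g medium
boiled egg, so smaller portions are ineligible rather than partially
swapped. "Highest protein" means absolute grams of protein in the served
portion (grams × density/100), not protein density. Two constraints modify
the greedy choice:

- **Seafood retention.** A seafood candidate is passed over if removing
  44 g would take the plan's weekly seafood grams below 226.8 g (eight
  ounce-equivalents) scaled by `kcal_target/2000`.
- **Variety.** A (subgroup, name) pair already chosen on an earlier day is
  demoted below unchosen alternatives — a soft penalty, not a prohibition,
  since repetition is discouraged rather than forbidden.

Ranking is lexicographic: (variety penalty, −protein grams, menu position).
The engine is pure (inputs never mutated), conserves total day grams
exactly, and reports per-day records with the selection rationale and the
signed nutrient delta `0.44·(egg − target)` densities. A per-day skip flag
lets callers exempt days (the published DASH menu has one day whose
as-given and substituted rows are identical; no reason is stated, so the
engine exposes the mechanism without guessing the cause). Mixed dishes are
treated as atomic: their densities embed the recipe, and the swap applies
to the dish as a whole. "Holding energy constant" is realized as the
gram-for-gram swap itself; the residual energy delta is computed and
reported, never forced to zero.

The shipped default egg profile (`data/egg_boiled.json`) carries generic
whole-boiled-egg composition reference values per 100 g (its 44 g vitamin D
content is 0.957 mcg); it is configuration, not published menu data, and
tests use synthetic profiles.

## Pricing

Daily price is linear in grams and additive over foods. Unpriced items are
handled by policy: `skip_and_log` omits them and records every omission
(the treatment given to a handful of small spice entries absent from the
source price database); `map_then_skip` first consults a user-supplied
two-column similarity mapping — a manual choice in the original analysis,
so it is data, not an algorithm; `error` aborts. Summary SDs are sample
(n−1) SDs, which is what reproduces the printed price SDs from the printed
dailies (HUSS 1.385 → printed 1.4). Substitution days are priced from
whatever foods the post-substitution plan contains, which matches the small
printed decreases.

## Comparison statistics

Three families mirror the published analysis: per-nutrient daily values at
α = 0.05/256, total FNI at 0.05/4, and prices at 0.05/4. Thresholds are
computed exactly (0.0001953…, 0.0125); a `printed_thresholds` switch
substitutes the truncated printed cutoffs (0.0001, 0.01) — conclusions are
identical either way on the packaged data. The published text does not say
whether "pairwise" meant paired-by-day or unpaired; the default is Welch's
unpaired test, which matches the published conclusion of no significant
differences in any family, and recomputes the HUSS price comparison to
p ≈ 0.9 against a printed 0.8 (the paired alternative gives p ≈ 0.04).
Pairing by day answers a different question — it detects the systematic
daily choline/vitamin D gain the substitution engineers by construction —
and is available as `TestMode.paired` (plus `pooled`). Degenerate inputs
(identical pairs) return t = 0, p = 1 by convention rather than NaN.

## Synthetic menu generator

`generate_plan` emulates the structure the analysis assumes: 7 days,
6–12 foods/day, ~2000 kcal/day (±15 %), ≥ 2 non-egg protein items of
≥ 44 g per day, seafood on 2 days, 25 % of protein items flagged as mixed
dishes. Densities and prices are log-normal — positive and right-skewed
like real composition data — with per-group (protein/seafood/other)
medians and sigmas that are explicitly configuration, not claims about real
foods. Energy is calibrated by uniformly rescaling portions (composition
preserved), then restoring the 44 g protein floor and re-balancing with the
non-protein portions. Food names are drawn from a small per-group pool so
the same protein source recurs across days and the variety rule is actually
exercised. A single seeded stream with fixed draw order makes plans fully
deterministic; prices use an offset stream so plan and price table can be
regenerated independently.

What the generator does *not* emulate: real NDSR food-composition
correlations (nutrients are drawn independently), recipes, or realistic
price–food associations. Passing tests therefore demonstrate the engine's
contracts (selection order, conservation laws, score algebra) — not that
any particular real menu would score identically.

`generate_calibrated_plan` rescales densities per nutrient so the
across-day mean equals `level × mean(DRI_F, DRI_M)`, giving closed-form
expected scores; the rescale factor carries a 1 + 1e-12 upward guard so a
mean intended to sit exactly at the reference is never an ulp under it.

## Known limitations and open findings

- Two cells of the published daily-totals table are internally
  inconsistent: the DASH as-given zinc dailies average 13.01 against a
  printed mean of 12.9 (Δ 0.114, just beyond the ±0.1 that 1-dp rounding
  can explain), and the HVEG egg-substitution choline dailies average
  562.93 against a printed 562.7 (Δ 0.229, likely a typo in the printed
  table). The two corresponding acceptance-suite cases fail by design and
  `analysis/01_check_nutrient_tables.py` flags the same cells; all other
  62 cells agree within rounding.
- Published total-score SDs and all printed p-values are not reconstructible
  from printed inputs (see above); only the qualitative non-significance
  conclusion is asserted.
- Annualized and regional cost extrapolations are out of scope: the printed
  figures are not consistent with any arithmetic derivable from the daily
  prices.
- Problem sizes: reproduction checks run on the 7-day fixtures; engine
  property checks use 100 seeded synthetic plans (selection oracle) and
  10–25 plans for conservation/delta properties, sizes at which the
  exhaustive oracle is exact and the whole suite stays fast.
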