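"""Pairwise t-tests with Bonferroni-adjusted significance thresholds.

Three comparison families mirror the published analysis: per-nutrient daily
values (alpha 0.05/256), total FNI scores (0.05/4), and daily menu prices
(0.05/4).  The test mode is configurable — Welch (default), pooled-variance
unpaired, or paired-by-day — because the source analysis does not state
which "pairwise" construction was used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import NUTRIENTS
from .io import TotalsTable


class TestMode(str, Enum):
    __test__ = False  # not a pytest collectable despite the Test* name

    paired = "paired"
    welch = "welch"
    pooled = "pooled"


#: Comparison counts used for the published Bonferroni thresholds.
NUTRIENT_FAMILY_COMPARISONS = 256  # 8 nutrients x 8 day-slots x 4 menus
SCORE_FAMILY_COMPARISONS = 4  # 1 pairwise comparison x 4 menus
PRICE_FAMILY_COMPARISONS = 4

#: Truncated thresholds as printed (0.05/256 -> 0.0001, 0.05/4 -> 0.01).
PRINTED_THRESHOLDS = {256: 0.0001, 4: 0.01}


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    family: str
    statistic: float
    df: float
    p_value: float
    alpha_adjusted: float
    significant: bool
    test_mode: TestMode


def bonferroni_alpha(base_alpha: float, n_comparisons: int) -> float:
    if not 0 < base_alpha < 1:
        raise ValueError("base_alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return base_alpha / n_comparisons


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: TestMode = TestMode.welch,
    label: str = "",
    family: str = "",
    alpha_adjusted: float = 0.05,
) -> ComparisonResult:
    """Two-sided t-test between two samples under the chosen mode."""
    mode = TestMode(mode)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if mode == TestMode.paired:
        if len(x) != len(y):
            raise ValueError("paired mode requires equal lengths")
        diffs = x - y
        if np.allclose(diffs, 0.0):
            # identical pairs: no evidence of a difference, by convention
            stat, p, df = 0.0, 1.0, float(len(x) - 1)
        else:
            res = sps.ttest_rel(x, y)
            stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        equal_var = mode == TestMode.pooled
        if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y):
            n = len(x) + len(y)
            stat, p = 0.0, 1.0
            df = float(n - 2)
        else:
            res = sps.ttest_ind(x, y, equal_var=equal_var)
            stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if math.isnan(p):
        stat, p = 0.0, 1.0
    return ComparisonResult(
        label=label,
        family=family,
        statistic=stat,
        df=df,
        p_value=p,
        alpha_adjusted=alpha_adjusted,
        significant=p < alpha_adjusted,
        test_mode=mode,
    )


def compare_conditions(
    totals_a: TotalsTable,
    totals_b: TotalsTable,
    prices_a: Sequence[float] | None = None,
    prices_b: Sequence[float] | None = None,
    fni_daily_a: Sequence[float] | None = None,
    fni_daily_b: Sequence[float] | None = None,
    mode: TestMode = TestMode.welch,
    base_alpha: float = 0.05,
    printed_thresholds: bool = False,
) -> list[ComparisonResult]:
    """Emit the three published comparison families for one menu.

    Per-nutrient daily values are tested at alpha/256; FNI totals and
    prices at alpha/4.  With ``printed_thresholds`` the truncated printed
    cutoffs (0.0001, 0.01) are used instead of the exact quotients.
    """
    if totals_a.days != totals_b.days:
        raise ValueError("mismatched day counts between conditions")

    def alpha_for(n: int) -> float:
        if printed_thresholds and n in PRINTED_THRESHOLDS:
            return PRINTED_THRESHOLDS[n]
        return bonferroni_alpha(base_alpha, n)

    results: list[ComparisonResult] = []
    a_nut = alpha_for(NUTRIENT_FAMILY_COMPARISONS)
    for nutrient in NUTRIENTS:
        results.append(
            t_test(
                totals_a.daily_amounts(nutrient),
                totals_b.daily_amounts(nutrient),
                mode=mode,
                label=f"{totals_a.menu_name}:{nutrient}",
                family="nutrient",
                alpha_adjusted=a_nut,
            )
        )
    a_score = alpha_for(SCORE_FAMILY_COMPARISONS)
    if fni_daily_a is not None and fni_daily_b is not None:
        results.append(
            t_test(
                fni_daily_a,
                fni_daily_b,
                mode=mode,
                label=f"{totals_a.menu_name}:fni_total",
                family="fni",
                alpha_adjusted=a_score,
            )
        )
    a_price = alpha_for(PRICE_FAMILY_COMPARISONS)
    if prices_a is not None and prices_b is not None:
        results.append(
            t_test(
                prices_a,
                prices_b,
                mode=mode,
                label=f"{totals_a.menu_name}:price",
                family="price",
                alpha_adjusted=a_price,
            )
        )
    return results
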