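"""Rank-based univariate screening of hospitalisation cost.

Cost distributions are heavily right-skewed, so group comparisons use rank
tests: Mann-Whitney U (normal approximation with tie-corrected variance) for
two-level factors and Kruskal-Wallis H (tie-corrected, chi-square reference)
for multi-level factors.  Results carry per-level counts, shares and rank
means in the shape of a standard screening table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "LevelStat",
    "RankTestResult",
    "mann_whitney",
    "kruskal_wallis",
    "screen_factors",
    "univariate_table",
    "percentage",
]

#: Factors screened by default, in report order.
DEFAULT_VARIABLES = (
    "sex",
    "age_band",
    "allergy",
    "social_insurance",
    "cc_level",
    "admission_route",
    "discharge_mode",
    "long_stay",
)

_LEVEL_ORDERS = {
    "sex": ("male", "female"),
    "age_band": ("0-17", "18-65", ">65"),
    "cc_level": ("MCC", "CC", "NonCC"),
    "admission_route": ("emergency", "outpatient_other"),
    "discharge_mode": ("home", "transfer", "death", "other"),
}


def percentage(part: float, total: float) -> float:
    """Share of ``part`` in ``total`` as a percentage."""
    if total == 0:
        raise InputError("total is zero")
    return 100.0 * part / total


@dataclass(frozen=True)
class LevelStat:
    level: str
    n: int
    share_pct: float
    rank_mean: float


@dataclass(frozen=True)
class RankTestResult:
    variable: str
    kind: str  # "Z", "H" or "U"
    statistic: float
    p_value: float
    levels: tuple[LevelStat, ...]
    alpha: float | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.alpha is None else bool(self.p_value < self.alpha)


def _level_stats(values_by_level: Mapping[str, np.ndarray]) -> tuple[LevelStat, ...]:
    all_values = np.concatenate(list(values_by_level.values()))
    ranks = stats.rankdata(all_values)  # midranks
    total = len(all_values)
    out = []
    start = 0
    for level, vals in values_by_level.items():
        k = len(vals)
        out.append(
            LevelStat(
                level=str(level),
                n=k,
                share_pct=percentage(k, total),
                rank_mean=float(ranks[start : start + k].mean()),
            )
        )
        start += k
    return tuple(out)


def mann_whitney(
    costs_a: Sequence[float],
    costs_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    continuity: bool = False,
    method: str = "asymptotic",
    alpha: float | None = None,
) -> RankTestResult:
    """Two-sample rank test of a location shift in cost.

    The asymptotic path computes midranks, the U statistic of the first
    group, and Z from the normal approximation with tie-corrected variance
    (continuity correction off by default); p is two-sided.  ``method=
    "exact"`` enumerates the permutation null instead (small samples, no
    normal approximation) and reports U as the statistic.
    """
    a = np.asarray(costs_a, dtype=float)
    b = np.asarray(costs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    level_stats = _level_stats({labels[0]: a, labels[1]: b})

    if method == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return RankTestResult(
            variable="", kind="U", statistic=float(res.statistic),
            p_value=float(res.pvalue), levels=level_stats, alpha=alpha,
        )
    if method != "asymptotic":
        raise ConfigurationError(f"unknown method {method!r}")

    big_n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:  # all observations tied
        z, p = 0.0, 1.0
    else:
        diff = u1 - n1 * n2 / 2.0
        if continuity and diff != 0:
            diff -= 0.5 * np.sign(diff)
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return RankTestResult(
        variable="", kind="Z", statistic=float(z), p_value=min(p, 1.0),
        levels=level_stats, alpha=alpha,
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float | None = None,
) -> RankTestResult:
    """Kruskal-Wallis H across >= 2 groups with tie correction; chi-square
    reference with k-1 degrees of freedom."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise InputError("need >= 2 nonempty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    level_stats = _level_stats(dict(zip(labels, arrays)))
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return RankTestResult(
        variable="", kind="H", statistic=float(h), p_value=float(p),
        levels=level_stats, alpha=alpha,
    )


def screen_factors(
    cohort: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    cost: str = "total_cost",
    alpha: float = 0.05,
) -> list[RankTestResult]:
    """One rank test per factor: Mann-Whitney for two observed levels,
    Kruskal-Wallis for more.  Boolean factors are reported as no/yes."""
    results = []
    for var in variables:
        if var not in cohort.columns:
            raise ConfigurationError(f"variable {var!r} not in cohort")
        col = cohort[var]
        if col.dtype == bool:
            col = col.map({False: "no", True: "yes"})
        order = _LEVEL_ORDERS.get(var)
        observed = list(pd.unique(col))
        if order:
            observed = [lv for lv in order if lv in observed] + [
                lv for lv in observed if lv not in order
            ]
        else:
            observed = sorted(observed, key=str)
        if len(observed) < 2:
            raise InputError(f"factor {var!r} has a single observed level")
        values = [cohort.loc[col == lv, cost].to_numpy() for lv in observed]
        if len(observed) == 2:
            res = mann_whitney(values[0], values[1],
                               labels=(str(observed[0]), str(observed[1])),
                               alpha=alpha)
        else:
            res = kruskal_wallis(values, labels=[str(lv) for lv in observed],
                                 alpha=alpha)
        results.append(
            RankTestResult(
                variable=var, kind=res.kind, statistic=res.statistic,
                p_value=res.p_value, levels=res.levels, alpha=alpha,
            )
        )
    return results


def los_summary(cohort: pd.DataFrame, los: str = "los") -> tuple[float, float]:
    """Descriptive mean and SD of length of stay for the screening report
    (LOS enters the tests only through the dichotomised >30-day factor)."""
    col = cohort[los].astype(float)
    return float(col.mean()), float(col.std(ddof=1))


def univariate_table(
    results: Sequence[RankTestResult],
    los_mean_sd: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Screening results as a flat report table (one row per factor level),
    optionally closed by a descriptive LOS mean ± SD row."""
    rows = []
    for res in results:
        for j, lv in enumerate(res.levels):
            rows.append({
                "variable": res.variable if j == 0 else "",
                "level": lv.level,
                "n": lv.n,
                "share_pct": round(lv.share_pct, 2),
                "rank_mean": round(lv.rank_mean, 2),
                "statistic_kind": res.kind if j == 0 else "",
                "statistic": round(res.statistic, 3) if j == 0 else np.nan,
                "p_value": res.p_value if j == 0 else np.nan,
                "significant": res.significant if j == 0 else None,
            })
    if los_mean_sd is not None:
        mean, sd = los_mean_sd
        rows.append({
            "variable": "los", "level": f"{mean:.2f}±{sd:.2f}",
            "n": sum(lv.n for lv in results[0].levels) if results else 0,
            "share_pct": np.nan, "rank_mean": np.nan,
            "statistic_kind": "", "statistic": np.nan,
            "p_value": np.nan, "significant": None,
        })
    return pd.DataFrame(rows)
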