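"""Group homogeneity validation and payment standards.

A candidate case-mix group is considered acceptably homogeneous when the
coefficient of variation (CV, sample SD over mean) of its costs is at most
1; a parent group with CV > 1 is heterogeneous enough to warrant
subdivision.  Between-group separation is checked with a Kruskal-Wallis
rank test.  The payment standard of a group is its median cost; the outlier
fence is the boxplot upper fence P75 + 1.5*IQR, and admissions strictly
above it are "excess" cases, counted and expressed as a rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .univariate import RankTestResult, kruskal_wallis, percentage

__all__ = [
    "GroupPayment",
    "PremiseResult",
    "GroupingValidation",
    "coefficient_of_variation",
    "premise_check",
    "upper_fence",
    "payment_standard",
    "validate_grouping",
    "payment_table",
]


def coefficient_of_variation(costs: Sequence[float]) -> float:
    """Sample (n-1) standard deviation divided by the mean; needs n >= 2 and
    a positive mean.  Scale-invariant: CV(k*x) = CV(x) for k > 0."""
    x = np.asarray(costs, dtype=float)
    if x.size < 2:
        raise InputError("CV needs at least 2 values")
    mean = float(x.mean())
    if mean <= 0:
        raise InputError("CV needs a positive mean")
    return float(x.std(ddof=1)) / mean


@dataclass(frozen=True)
class PremiseResult:
    """Whether a parent group is heterogeneous enough to subdivide."""

    cv: float
    subdivide: bool


def premise_check(costs: Sequence[float]) -> PremiseResult:
    """Recommend subdivision iff the cohort CV is strictly greater than 1."""
    cv = coefficient_of_variation(costs)
    return PremiseResult(cv=cv, subdivide=cv > 1.0)


def upper_fence(p75: float, iqr: float) -> float:
    """Boxplot upper fence: 75th percentile plus 1.5 times the IQR."""
    return p75 + 1.5 * iqr


@dataclass(frozen=True)
class GroupPayment:
    """Per-group payment summary: standard cost (median), quartiles, the
    upper fence and the excess-case count/rate."""

    group_id: str
    description: str
    n: int
    cv: float | None  # None for singleton groups (undefined)
    median: float
    p25: float
    p75: float
    excess_n: int

    @property
    def iqr(self) -> float:
        return self.p75 - self.p25

    @property
    def upper_limit(self) -> float:
        return upper_fence(self.p75, self.iqr)

    @property
    def excess_rate(self) -> float:
        return percentage(self.excess_n, self.n)

    @classmethod
    def from_summary(
        cls,
        p75: float,
        iqr: float,
        n: int = 0,
        excess_n: int = 0,
        median: float = float("nan"),
        cv: float | None = None,
        group_id: str = "",
        description: str = "",
    ) -> "GroupPayment":
        """Build from printed summary quantities (P75 and IQR) rather than
        raw costs; the fence rule is evaluated from these inputs."""
        return cls(
            group_id=group_id, description=description, n=n, cv=cv,
            median=median, p25=p75 - iqr, p75=p75, excess_n=excess_n,
        )


def payment_standard(
    costs: Sequence[float],
    group_id: str = "",
    description: str = "",
    quantile_method: str = "linear",
) -> GroupPayment:
    """Payment summary of one group's costs.

    Quantiles use the configured convention (numpy ``method``, default
    linear interpolation); the upper limit is P75 + 1.5*IQR and excess cases
    are those strictly above it.  Reported currency rounds at 2 decimals,
    half to even.
    """
    x = np.asarray(costs, dtype=float)
    if x.size == 0:
        raise InputError("empty group")
    p25, med, p75 = (
        float(np.quantile(x, q, method=quantile_method)) for q in (0.25, 0.5, 0.75)
    )
    limit = upper_fence(p75, p75 - p25)
    return GroupPayment(
        group_id=group_id,
        description=description,
        n=int(x.size),
        cv=coefficient_of_variation(x) if x.size >= 2 else None,
        median=round(med, 2),
        p25=round(p25, 2),
        p75=round(p75, 2),
        excess_n=int((x > limit).sum()),
    )


@dataclass
class GroupingValidation:
    """CV-rule verdict and Kruskal-Wallis separation across groups."""

    group_cv: pd.Series  # CV per group (NaN for singletons)
    n_groups: int
    n_homogeneous: int  # groups with CV <= 1
    singleton_groups: list[str]
    kruskal: RankTestResult

    @property
    def all_homogeneous(self) -> bool:
        return self.n_homogeneous == self.n_groups - len(self.singleton_groups)


def validate_grouping(
    costs: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
) -> GroupingValidation:
    """Per-group CV, count of groups meeting the CV <= 1 rule, and a
    Kruskal-Wallis test of between-group cost differences.

    Singleton groups are flagged and their CV reported as undefined; the
    rank test requires at least two groups.
    """
    frame = pd.DataFrame({"cost": np.asarray(costs, dtype=float), "group": list(groups)})
    cvs = {}
    singletons = []
    for gid, sub in frame.groupby("group", sort=True):
        if len(sub) < 2:
            singletons.append(str(gid))
            cvs[gid] = np.nan
        else:
            cvs[gid] = coefficient_of_variation(sub["cost"])
    by_group = [sub["cost"].to_numpy() for _, sub in frame.groupby("group", sort=True)]
    labels = [str(gid) for gid, _ in frame.groupby("group", sort=True)]
    kw = kruskal_wallis(by_group, labels=labels, alpha=alpha)
    series = pd.Series(cvs).sort_index()
    n_hom = int((series.dropna() <= 1.0).sum())
    return GroupingValidation(
        group_cv=series,
        n_groups=len(series),
        n_homogeneous=n_hom,
        singleton_groups=singletons,
        kruskal=kw,
    )


def payment_table(payments: Sequence[GroupPayment]) -> pd.DataFrame:
    """Per-group payment report (group, description, n, CV, standard cost,
    IQR, P75, upper limit, excess count and rate)."""
    return pd.DataFrame(
        [
            {
                "group": p.group_id,
                "description": p.description,
                "n": p.n,
                "cv": round(p.cv, 2) if p.cv is not None else np.nan,
                "median": round(p.median, 2),
                "iqr": round(p.iqr, 2),
                "p75": round(p.p75, 2),
                "upper_limit": round(p.upper_limit, 2),
                "excess_n": p.excess_n,
                "excess_rate_pct": round(p.excess_rate, 2),
            }
            for p in payments
        ]
    )
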