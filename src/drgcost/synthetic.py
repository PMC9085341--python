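"""Seeded synthetic discharge-abstract cohorts.

The generator emulates the statistical structure of a single-ADRG inpatient
cohort (cerebral ischemic disease, three admission years): the marginal
category mix of the demographic/administrative factors, a multiplicative
log-link cost model with gamma noise, a right-skewed LOS distribution
truncated to 1-60 days, and an eight-way cost-component split.  Covariates
are drawn independently — only the marginal prevalences are targeted — and
the expected cost of a record is

    E[cost] = baseline_mean * prod(multiplier of each drawn factor level),

with the realised cost gamma-distributed around that mean at a constant
shape.  ``baseline_mean`` and ``gamma_shape`` are calibrated in closed form
so the cohort mean and coefficient of variation hit configurable targets
(defaults 17,206.09 currency units and 1.18).

Synthetic code tables (MCC/CC inclusion lists with sparse primary-diagnosis
exclusions, plus a principal-code scheme) stand in for the official
grouping-scheme dictionaries, which are not redistributable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .records import (
    AGE_BANDS,
    CC_LEVELS,
    COST_COMPONENTS,
    CCLevel,
    CCTable,
    InpatientRecord,
)

__all__ = [
    "GeneratorConfig",
    "CodeUniverse",
    "default_config",
    "generate_cohort",
    "generate_cc_tables",
    "generate_study_cohort",
    "expected_cost",
]

#: Calibration targets for the default cohort.
TARGET_MEAN = 17_206.09
TARGET_CV = 1.18

#: Marginal prevalences of the emulated cohort (category -> probability).
CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.3822, "male": 0.6178},
    "age_band": {"0-17": 0.0131, "18-65": 0.4364, ">65": 0.5505},
    "allergy": {"no": 0.5135, "yes": 0.4865},
    "social_insurance": {"yes": 0.1163, "no": 0.8837},
    "admission_route": {"outpatient_other": 0.4518, "emergency": 0.5482},
    "discharge_mode": {"home": 0.9666, "transfer": 0.0121, "death": 0.0175, "other": 0.0038},
    "cc_level": {"NonCC": 0.1989, "CC": 0.5769, "MCC": 0.2243},
    "long_stay": {"no": 0.9591, "yes": 0.0409},
}

#: Multiplicative effects on expected cost (reference levels implicitly 1).
EFFECT_MULTIPLIERS: dict[str, dict[str, float]] = {
    "sex": {"male": 1.05},
    "age_band": {"18-65": 2.22, ">65": 2.63},
    "admission_route": {"emergency": 1.20},
    "cc_level": {"CC": 1.48, "MCC": 2.25},
    "long_stay": {"yes": 4.23},
    "discharge_mode": {"transfer": 1.76, "death": 1.55, "other": 1.35},
}

#: Per-year cohort sizes and per-category mean costs of the emulated cohort;
#: used for the admission-year mix and the cost-component shares.
YEAR_COMPOSITION: dict[int, tuple[int, dict[str, float]]] = {
    2018: (1892, {
        "diagnosis": 7002.85, "drug": 3762.32, "comprehensive_service": 2580.27,
        "rehabilitation": 1065.62, "consumables": 780.23, "treatment": 575.62,
        "blood_products": 18.82, "other": 619.28,
    }),
    2019: (1909, {
        "diagnosis": 6944.94, "drug": 4341.63, "comprehensive_service": 2514.80,
        "rehabilitation": 988.00, "consumables": 746.37, "treatment": 698.46,
        "blood_products": 88.96, "other": 1098.63,
    }),
    2020: (1403, {
        "diagnosis": 7409.75, "drug": 4026.44, "comprehensive_service": 2491.84,
        "rehabilitation": 1191.05, "consumables": 909.14, "treatment": 782.53,
        "blood_products": 176.71, "other": 1005.46,
    }),
}

LOS_MEAN = 10.70
LOS_SD = 8.61
LOS_RANGE = (1, 60)


def _normalise(probs: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(probs.values()))
    return {k: v / total for k, v in probs.items()}


def _pooled_component_shares() -> dict[str, float]:
    """Cost-component shares pooled across the three emulated years."""
    totals = {c: 0.0 for c in COST_COMPONENTS}
    n_all = 0
    for n, means in YEAR_COMPOSITION.values():
        n_all += n
        for c in COST_COMPONENTS:
            totals[c] += n * means[c]
    grand = sum(totals.values())
    return {c: totals[c] / grand for c in COST_COMPONENTS}


def _year_probs() -> dict[int, float]:
    n_all = sum(n for n, _ in YEAR_COMPOSITION.values())
    return {y: n / n_all for y, (n, _) in YEAR_COMPOSITION.items()}


@dataclass
class GeneratorConfig:
    """Everything the cohort generator needs; see module docstring."""

    n: int = 5204
    seed: int = 0
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CATEGORY_PROBS.items()}
    )
    effect_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in EFFECT_MULTIPLIERS.items()}
    )
    baseline_mean: float | None = None  # calibrated from target_mean if None
    gamma_shape: float | None = None  # calibrated from target_cv if None
    target_mean: float = TARGET_MEAN
    target_cv: float = TARGET_CV
    los_mean: float = LOS_MEAN
    los_sd: float = LOS_SD
    los_range: tuple[int, int] = LOS_RANGE
    component_shares: dict[str, float] = field(
        default_factory=_pooled_component_shares
    )
    component_concentration: float = 300.0  # Dirichlet jitter of the split
    year_probs: dict[int, float] = field(default_factory=_year_probs)
    n_codes: int = 30

    def __post_init__(self):
        for var, probs in self.category_probs.items():
            if any(p < 0 for p in probs.values()) or sum(probs.values()) <= 0:
                raise ConfigurationError(f"bad probabilities for {var}")
            self.category_probs[var] = _normalise(probs)
        for var, mults in self.effect_multipliers.items():
            if any(m <= 0 for m in mults.values()):
                raise ConfigurationError(f"non-positive multiplier for {var}")
        if abs(sum(self.component_shares.values()) - 1) > 1e-6:
            raise ConfigurationError("component shares must sum to 1")
        self.year_probs = _normalise(self.year_probs)
        if self.baseline_mean is None:
            self.baseline_mean = self.target_mean / self._mean_multiplier()
        if self.gamma_shape is None:
            self.gamma_shape = self._calibrated_shape()
        if self.gamma_shape <= 0:
            raise ConfigurationError("gamma_shape must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")

    # -- closed-form calibration ------------------------------------------
    def _factor_moments(self) -> tuple[float, float]:
        """E[R] and E[R^2] of the product R of factor multipliers, using the
        independence of the drawn factors."""
        e1 = e2 = 1.0
        for var, mults in self.effect_multipliers.items():
            probs = self.category_probs[var]
            m1 = sum(p * mults.get(level, 1.0) for level, p in probs.items())
            m2 = sum(p * mults.get(level, 1.0) ** 2 for level, p in probs.items())
            e1 *= m1
            e2 *= m2
        return e1, e2

    def _mean_multiplier(self) -> float:
        return self._factor_moments()[0]

    def _calibrated_shape(self) -> float:
        """Shape k such that the marginal cohort CV hits ``target_cv``.

        With cost | R ~ Gamma(mean b*R, shape k) and R the multiplier
        product:  CV^2 + 1 = (1 + 1/k) * E[R^2] / E[R]^2, so
        k = 1 / ((1 + CV^2) * E[R]^2 / E[R^2] - 1).
        """
        e1, e2 = self._factor_moments()
        denom = (1.0 + self.target_cv**2) * e1**2 / e2 - 1.0
        if denom <= 0:
            raise ConfigurationError(
                "target CV not attainable: covariate mix alone exceeds it"
            )
        return 1.0 / denom


def default_config(n: int = 5204, seed: int = 0, **overrides) -> GeneratorConfig:
    """The study conditions: emulated prevalences, cost multipliers and the
    mean/CV calibration targets."""
    return GeneratorConfig(n=n, seed=seed, **overrides)


def expected_cost(config: GeneratorConfig, levels: Mapping[str, str]) -> float:
    """Model expectation of cost for a record at the given factor levels."""
    r = 1.0
    for var, mults in config.effect_multipliers.items():
        r *= mults.get(levels.get(var, ""), 1.0)
    return config.baseline_mean * r


# ---------------------------------------------------------------------------
# synthetic code tables


@dataclass(frozen=True)
class CodeUniverse:
    """Synthetic diagnosis/procedure code universe backing a cohort."""

    primary_codes: tuple[str, ...]
    procedure_codes: tuple[str, ...]
    mcc_codes: tuple[str, ...]
    cc_codes: tuple[str, ...]
    neutral_codes: tuple[str, ...]

    @property
    def scheme_codes(self) -> frozenset[str]:
        return frozenset(self.primary_codes) | frozenset(self.procedure_codes)


def generate_cc_tables(
    seed: int = 0, n_codes: int = 30
) -> tuple[CCTable, CodeUniverse]:
    """Synthetic MCC/CC inclusion tables, a sparse exclusion map and the code
    universe (principal diagnoses, procedures, secondary diagnoses).

    The ``n_codes`` secondary codes are split roughly evenly into MCC / CC /
    neutral sets (at least one each); about 20% of the inclusion codes get
    one excluded principal diagnosis.
    """
    if n_codes < 3:
        raise ConfigurationError("n_codes must be >= 3")
    rng = np.random.default_rng(seed)
    secondary = [f"S{i:03d}" for i in range(n_codes)]
    third = n_codes // 3
    mcc = tuple(secondary[:third]) or (secondary[0],)
    cc = tuple(secondary[third : 2 * third]) or (secondary[1],)
    neutral = tuple(secondary[2 * third :])
    primary = tuple(f"P{i:02d}" for i in range(6))
    procedures = tuple(f"OP{i:02d}" for i in range(4))
    n_excl = int(0.2 * (len(mcc) + len(cc)))
    exclusion: dict[str, frozenset[str]] = {}
    if n_excl > 0:
        pool = list(mcc + cc)
        chosen = rng.choice(len(pool), size=min(n_excl, len(pool)), replace=False)
        for idx in sorted(chosen):
            exclusion[pool[idx]] = frozenset(
                {primary[int(rng.integers(len(primary)))]}
            )
    table = CCTable(frozenset(mcc), frozenset(cc), exclusion)
    return table, CodeUniverse(primary, procedures, mcc, cc, neutral)


# ---------------------------------------------------------------------------
# cohort generation


def _draw_levels(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()))
    return rng.choice(levels, size=n, p=p)


def _draw_los(rng, config: GeneratorConfig, long_stay: np.ndarray) -> np.ndarray:
    """LOS from a moment-matched log-normal, truncated to [1, 30] for ordinary
    stays and [31, 60] for long stays, rounded to whole days."""
    sigma2 = math.log(1.0 + (config.los_sd / config.los_mean) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(config.los_mean) - sigma2 / 2.0
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    lo, hi = config.los_range
    split = 30.5
    bounds = np.where(long_stay, split, lo - 0.5), np.where(long_stay, hi + 0.49, split)
    flo = dist.cdf(bounds[0])
    fhi = dist.cdf(bounds[1])
    u = rng.uniform(flo, fhi)
    los = np.rint(dist.ppf(u)).astype(int)
    return np.clip(los, np.where(long_stay, 31, lo), np.where(long_stay, hi, 30))


def _secondary_codes(
    rng,
    cc_level: np.ndarray,
    primary: np.ndarray,
    table: CCTable,
    universe: CodeUniverse,
) -> list[tuple[str, ...]]:
    """Secondary-diagnosis lists consistent with each record's drawn severity.

    MCC records carry one qualifying MCC code (not voided by the record's
    principal diagnosis) plus neutral/CC extras; CC records one qualifying CC
    code plus neutral extras; Non-CC records neutral extras only.
    """
    n = len(cc_level)
    mcc_pool = list(universe.mcc_codes)
    cc_pool = list(universe.cc_codes)
    neutral_pool = list(universe.neutral_codes) or [""]

    def qualifying(pool: list[str], prim: str, idx: int) -> str:
        code = pool[idx % len(pool)]
        if prim in table.excluded_primaries(code):
            for off in range(1, len(pool) + 1):
                alt = pool[(idx + off) % len(pool)]
                if prim not in table.excluded_primaries(alt):
                    return alt
        return code

    main_idx = rng.integers(0, 1 << 30, size=n)
    extra_n = rng.integers(0, 3, size=n)
    extra_idx = rng.integers(0, 1 << 30, size=(n, 2))
    out: list[tuple[str, ...]] = []
    for i in range(n):
        codes: list[str] = []
        if cc_level[i] == CCLevel.MCC.value:
            codes.append(qualifying(mcc_pool, primary[i], int(main_idx[i])))
        elif cc_level[i] == CCLevel.CC.value:
            codes.append(qualifying(cc_pool, primary[i], int(main_idx[i])))
        for j in range(int(extra_n[i])):
            extra = neutral_pool[int(extra_idx[i, j]) % len(neutral_pool)]
            if extra:
                codes.append(extra)
        out.append(tuple(codes))
    return out


def generate_cohort(
    config: GeneratorConfig,
    table: CCTable | None = None,
    universe: CodeUniverse | None = None,
) -> list[InpatientRecord]:
    """Draw a cohort of ``config.n`` admissions; deterministic in ``config.seed``.

    Covariates are independent draws from ``category_probs``; cost is gamma
    around the multiplicative expectation; LOS is drawn consistently with the
    long-stay indicator; cost components follow a Dirichlet-jittered split of
    the configured shares, adding up to the total to the cent.
    """
    if table is None or universe is None:
        table, universe = generate_cc_tables(seed=config.seed, n_codes=config.n_codes)
    rng = np.random.default_rng(config.seed)
    n = config.n
    cp = config.category_probs

    sex = _draw_levels(rng, cp["sex"], n)
    age_band = _draw_levels(rng, cp["age_band"], n)
    allergy = _draw_levels(rng, cp["allergy"], n) == "yes"
    insurance = _draw_levels(rng, cp["social_insurance"], n) == "yes"
    route = _draw_levels(rng, cp["admission_route"], n)
    discharge = _draw_levels(rng, cp["discharge_mode"], n)
    cc_level = _draw_levels(rng, cp["cc_level"], n)
    long_stay = _draw_levels(rng, cp["long_stay"], n) == "yes"
    year = _draw_levels(rng, {str(y): p for y, p in config.year_probs.items()}, n).astype(int)

    # ages uniform inside the drawn band (0-17, 18-65, 66-99)
    age = np.empty(n, dtype=int)
    for band, lo, hi in (("0-17", 0, 17), ("18-65", 18, 65), (">65", 66, 99)):
        mask = age_band == band
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    los = _draw_los(rng, config, long_stay)

    levels = {
        "sex": sex,
        "age_band": age_band,
        "admission_route": route,
        "cc_level": cc_level,
        "discharge_mode": discharge,
        "long_stay": np.where(long_stay, "yes", "no"),
        "social_insurance": np.where(insurance, "yes", "no"),
        "allergy": np.where(allergy, "yes", "no"),
    }
    mu = np.full(n, config.baseline_mean)
    for var, mults in config.effect_multipliers.items():
        arr = levels[var]
        factor = np.ones(n)
        for level, m in mults.items():
            factor[arr == level] = m
        mu *= factor
    shape = config.gamma_shape
    cost = rng.gamma(shape, mu / shape)
    cost = np.maximum(np.round(cost, 2), 0.01)

    alpha = np.array(
        [config.component_shares[c] for c in COST_COMPONENTS]
    ) * config.component_concentration
    props = rng.dirichlet(alpha, size=n)
    comps = np.round(props * cost[:, None], 2)
    # force exact closure on the largest component (diagnosis)
    resid = np.round(cost - comps.sum(axis=1), 2)
    comps[:, 0] = np.round(comps[:, 0] + resid, 2)
    comps[:, 0] = np.maximum(comps[:, 0], 0.0)
    cost = np.round(comps.sum(axis=1), 2)  # re-close after any clipping

    primary = rng.choice(np.array(universe.primary_codes, dtype=object), size=n)
    n_proc = rng.integers(0, 3, size=n)
    proc_idx = rng.integers(0, len(universe.procedure_codes), size=(n, 2))
    secondary = _secondary_codes(rng, cc_level, primary, table, universe)

    records: list[InpatientRecord] = []
    for i in range(n):
        procs = tuple(
            universe.procedure_codes[proc_idx[i, j]] for j in range(int(n_proc[i]))
        )
        records.append(
            InpatientRecord(
                record_id=f"R{i:06d}",
                sex=str(sex[i]),
                age=int(age[i]),
                allergy=bool(allergy[i]),
                social_insurance=bool(insurance[i]),
                admission_route=str(route[i]),
                discharge_mode=str(discharge[i]),
                admission_year=int(year[i]),
                los=int(los[i]),
                primary_dx=str(primary[i]),
                secondary_dx=secondary[i],
                procedures=procs,
                total_cost=float(cost[i]),
                cost_components={
                    c: float(comps[i, k]) for k, c in enumerate(COST_COMPONENTS)
                },
            )
        )
    return records


def generate_study_cohort(
    seed: int = 0,
) -> tuple[list[InpatientRecord], CCTable, CodeUniverse]:
    """A raw cohort of 6214 admissions engineered so the four exclusion
    criteria retain 5204: 300 records with a blanked total cost, 301 with a
    principal code outside the scheme, 301 with LOS above 60 days, and a
    1st/99th-percentile cost trim removing 108 of the 5312 clean survivors.
    """
    config = default_config(n=6214, seed=seed)
    table, universe = generate_cc_tables(seed=seed, n_codes=config.n_codes)
    records = generate_cohort(config, table, universe)
    clean, dirty = records[:5312], records[5312:]
    rng = np.random.default_rng(seed + 1)
    contaminated: list[InpatientRecord] = []
    for k, r in enumerate(dirty):
        if k < 300:
            contaminated.append(replace(r, total_cost=None))
        elif k < 601:
            contaminated.append(replace(r, primary_dx="XX_BAD"))
        else:
            contaminated.append(replace(r, los=int(rng.integers(61, 91))))
    merged = clean + contaminated
    order = rng.permutation(len(merged))
    return [merged[i] for i in order], table, universe
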