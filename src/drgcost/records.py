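"""Discharge-abstract domain types, I/O, cleaning and severity assignment.

The unit of analysis is one inpatient admission ("discharge abstract"):
demographics, admission/discharge attributes, diagnosis and procedure codes,
length of stay (LOS), the total hospitalisation cost and its eight component
categories.  Severity is summarised by the comorbidity/complication (CC)
level: a case is MCC (major comorbidity or complication) if any secondary
diagnosis is on the MCC inclusion list and the primary diagnosis does not
void it via the exclusion list; otherwise CC by the same rule over the CC
list; otherwise Non-CC.

Cleaning applies four exclusion criteria in a fixed order — missing/invalid
items, principal code outside the grouping scheme, LOS above a cap (default
60 days), and a cost percentile trim (default 1st/99th, computed on the
cohort that survives the first three criteria) — and accounts for every
input record under the first criterion it violates.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, PipelineError

__all__ = [
    "COST_COMPONENTS",
    "SEX_LEVELS",
    "ADMISSION_ROUTES",
    "DISCHARGE_MODES",
    "AGE_BANDS",
    "CCLevel",
    "InpatientRecord",
    "CCTable",
    "DerivedFeatures",
    "ExclusionLog",
    "RowIssue",
    "ParseResult",
    "read_records",
    "write_records",
    "read_cc_tables",
    "write_cc_tables",
    "read_scheme_codes",
    "write_scheme_codes",
    "assign_cc_level",
    "apply_exclusions",
    "derive_features",
    "age_band_of",
    "cohort_frame",
]

# The eight cost components of the national discharge-abstract cost breakdown.
COST_COMPONENTS = (
    "diagnosis",
    "drug",
    "comprehensive_service",
    "rehabilitation",
    "consumables",
    "treatment",
    "blood_products",
    "other",
)

SEX_LEVELS = ("female", "male")
ADMISSION_ROUTES = ("outpatient_other", "emergency")
DISCHARGE_MODES = ("home", "transfer", "death", "other")
AGE_BANDS = ("0-17", "18-65", ">65")

#: Age-band upper bounds (inclusive): 0-17, 18-65, >65.
_AGE_BAND_EDGES = (17, 65)

#: Default absolute tolerance (currency units) for "components sum to total".
COMPONENT_SUM_TOL = 1.0


class CCLevel(str, Enum):
    """Comorbidity/complication severity level of an admission."""

    MCC = "MCC"
    CC = "CC"
    NON_CC = "NonCC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CC_LEVELS = (CCLevel.NON_CC.value, CCLevel.CC.value, CCLevel.MCC.value)


@dataclass(frozen=True)
class InpatientRecord:
    """One admission.  Fields may be ``None`` after a lenient parse; such
    records are counted under the missing-items exclusion criterion."""

    record_id: str
    sex: str | None
    age: int | None
    allergy: bool | None
    social_insurance: bool | None
    admission_route: str | None
    discharge_mode: str | None
    admission_year: int | None
    los: int | None
    primary_dx: str | None
    secondary_dx: tuple[str, ...] = ()
    procedures: tuple[str, ...] = ()
    total_cost: float | None = None
    cost_components: Mapping[str, float] = field(default_factory=dict)

    _REQUIRED = (
        "record_id",
        "sex",
        "age",
        "allergy",
        "social_insurance",
        "admission_route",
        "discharge_mode",
        "admission_year",
        "los",
        "primary_dx",
        "total_cost",
    )

    def missing_fields(self) -> list[str]:
        """Names of required fields that are absent or blank.

        Secondary diagnoses and procedures may be legitimately empty and are
        never reported here.  Missing cost components count as missing.
        """
        out = [
            name
            for name in self._REQUIRED
            if getattr(self, name) is None or getattr(self, name) == ""
        ]
        if any(self.cost_components.get(c) is None for c in COST_COMPONENTS):
            out.append("cost_components")
        return out

    def problems(self, component_tol: float = COMPONENT_SUM_TOL) -> list[str]:
        """Invariant violations for a fully populated record."""
        missing = self.missing_fields()
        if missing:
            return [f"missing: {', '.join(missing)}"]
        probs: list[str] = []
        if self.sex not in SEX_LEVELS:
            probs.append(f"sex not in {SEX_LEVELS}: {self.sex!r}")
        if self.age < 0:
            probs.append("age < 0")
        if self.admission_route not in ADMISSION_ROUTES:
            probs.append(f"admission_route not in {ADMISSION_ROUTES}")
        if self.discharge_mode not in DISCHARGE_MODES:
            probs.append(f"discharge_mode not in {DISCHARGE_MODES}")
        if self.los < 1:
            probs.append("los < 1")
        if self.total_cost <= 0:
            probs.append("total_cost <= 0")
        if any(v < 0 for v in self.cost_components.values()):
            probs.append("negative cost component")
        csum = sum(self.cost_components.get(c, 0.0) for c in COST_COMPONENTS)
        if abs(csum - self.total_cost) > component_tol:
            probs.append(
                f"components sum {csum:.2f} != total {self.total_cost:.2f}"
            )
        return probs

    def validate(self, component_tol: float = COMPONENT_SUM_TOL) -> None:
        probs = self.problems(component_tol)
        if probs:
            raise InputError(
                f"record {self.record_id}: " + "; ".join(probs)
            )


@dataclass(frozen=True)
class CCTable:
    """MCC/CC inclusion sets plus per-code primary-diagnosis exclusion sets.

    A secondary diagnosis qualifies a case for the MCC (or CC) level only if
    the primary diagnosis is not in that code's exclusion set.
    """

    mcc_codes: frozenset[str]
    cc_codes: frozenset[str]
    exclusion: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        overlap = self.mcc_codes & self.cc_codes
        if overlap:
            raise InputError(
                f"MCC and CC inclusion sets overlap: {sorted(overlap)}"
            )

    def excluded_primaries(self, secondary: str) -> frozenset[str]:
        return self.exclusion.get(secondary, frozenset())


@dataclass(frozen=True)
class DerivedFeatures:
    """Grouping features derived from a cleaned record."""

    age_band: str
    long_stay: bool
    cc_level: CCLevel


@dataclass
class ExclusionLog:
    """Per-criterion exclusion accounting; each record is counted once,
    under the first criterion it violates."""

    input_n: int
    counts: dict[str, int]
    retained_n: int

    CRITERIA = (
        "missing_fields",
        "code_not_in_scheme",
        "los_gt_60",
        "cost_percentile_trim",
    )

    def check(self) -> None:
        if self.input_n - sum(self.counts.values()) != self.retained_n:
            raise PipelineError("exclusion log does not add up")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "input_n": self.input_n,
            "excluded": self.counts,
            "retained_n": self.retained_n,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# delimited I/O

#: canonical field -> default column name (identity, minus the list fields)
DEFAULT_SCHEMA = {
    "record_id": "record_id",
    "sex": "sex",
    "age": "age",
    "allergy": "allergy",
    "social_insurance": "social_insurance",
    "admission_route": "admission_route",
    "discharge_mode": "discharge_mode",
    "admission_year": "admission_year",
    "los": "los",
    "primary_dx": "primary_dx",
    "secondary_dx": "secondary_dx",
    "procedures": "procedures",
    "total_cost": "total_cost",
    **{f"cost_{c}": f"cost_{c}" for c in COST_COMPONENTS},
}

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


@dataclass(frozen=True)
class RowIssue:
    row: int
    field: str | None
    message: str


@dataclass
class ParseResult:
    records: list[InpatientRecord]
    issues: list[RowIssue]


def _parse_bool(s: str) -> bool:
    t = s.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_list(s: str) -> tuple[str, ...]:
    return tuple(tok for tok in (t.strip() for t in s.split(";")) if tok)


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> ParseResult:
    """Read a delimited cohort file into validated records.

    Malformed cells are reported as :class:`RowIssue` entries (0-based data
    row index) and leave the corresponding field ``None``; the row itself is
    kept so the cleaning stage can account for it under the missing-items
    criterion.  A required column absent from the header raises
    :class:`ConfigurationError`.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing_cols = [col for col in schema.values() if col not in header]
        if missing_cols:
            raise ConfigurationError(
                f"missing required columns: {missing_cols}"
            )
        records: list[InpatientRecord] = []
        issues: list[RowIssue] = []
        for i, row in enumerate(reader):
            values: dict[str, object] = {}

            def grab(fname, conv, required=True):
                raw = (row.get(schema[fname]) or "").strip()
                if raw == "":
                    if required:
                        issues.append(RowIssue(i, fname, "blank"))
                    return None
                try:
                    return conv(raw)
                except (ValueError, TypeError) as exc:
                    issues.append(RowIssue(i, fname, str(exc)))
                    return None

            values["record_id"] = grab("record_id", str) or f"row{i}"
            values["sex"] = grab("sex", str)
            values["age"] = grab("age", int)
            values["allergy"] = grab("allergy", _parse_bool)
            values["social_insurance"] = grab("social_insurance", _parse_bool)
            values["admission_route"] = grab("admission_route", str)
            values["discharge_mode"] = grab("discharge_mode", str)
            values["admission_year"] = grab("admission_year", int)
            values["los"] = grab("los", int)
            values["primary_dx"] = grab("primary_dx", str)
            values["secondary_dx"] = grab("secondary_dx", _parse_list, required=False) or ()
            values["procedures"] = grab("procedures", _parse_list, required=False) or ()
            values["total_cost"] = grab("total_cost", float)
            comps = {}
            for c in COST_COMPONENTS:
                v = grab(f"cost_{c}", float)
                if v is not None:
                    comps[c] = v
            values["cost_components"] = comps
            records.append(InpatientRecord(**values))
    return ParseResult(records, issues)


def write_records(
    records: Iterable[InpatientRecord],
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write records as delimited UTF-8 with header; currency at 2 decimals."""
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    cols = list(schema.values())
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for r in records:
            row = [
                r.record_id,
                r.sex or "",
                "" if r.age is None else r.age,
                "" if r.allergy is None else int(r.allergy),
                "" if r.social_insurance is None else int(r.social_insurance),
                r.admission_route or "",
                r.discharge_mode or "",
                "" if r.admission_year is None else r.admission_year,
                "" if r.los is None else r.los,
                r.primary_dx or "",
                ";".join(r.secondary_dx),
                ";".join(r.procedures),
                "" if r.total_cost is None else f"{r.total_cost:.2f}",
            ]
            for c in COST_COMPONENTS:
                v = r.cost_components.get(c)
                row.append("" if v is None else f"{v:.2f}")
            writer.writerow(row)


def read_cc_tables(
    inclusion_path: str | Path, exclusion_path: str | Path | None = None
) -> CCTable:
    """Read the MCC/CC inclusion table (columns ``code,level``) and the
    optional exclusion table (columns ``secondary_code,excluded_primary_code``)."""
    mcc, cc = set(), set()
    with Path(inclusion_path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            level = row["level"].strip().upper()
            if level == "MCC":
                mcc.add(row["code"].strip())
            elif level == "CC":
                cc.add(row["code"].strip())
            else:
                raise ConfigurationError(f"unknown CC level {row['level']!r}")
    exclusion: dict[str, set[str]] = {}
    if exclusion_path is not None and Path(exclusion_path).exists():
        with Path(exclusion_path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                exclusion.setdefault(row["secondary_code"].strip(), set()).add(
                    row["excluded_primary_code"].strip()
                )
    return CCTable(
        frozenset(mcc),
        frozenset(cc),
        {k: frozenset(v) for k, v in exclusion.items()},
    )


def write_cc_tables(
    table: CCTable, inclusion_path: str | Path, exclusion_path: str | Path
) -> None:
    with Path(inclusion_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "level"])
        for code in sorted(table.mcc_codes):
            w.writerow([code, "MCC"])
        for code in sorted(table.cc_codes):
            w.writerow([code, "CC"])
    with Path(exclusion_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["secondary_code", "excluded_primary_code"])
        for sec in sorted(table.exclusion):
            for prim in sorted(table.exclusion[sec]):
                w.writerow([sec, prim])


def read_scheme_codes(path: str | Path) -> frozenset[str]:
    """Single-column (``code``) file of admissible principal dx/procedure codes."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return frozenset(row["code"].strip() for row in csv.DictReader(fh))


def write_scheme_codes(codes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["code"])
        for code in sorted(codes):
            w.writerow([code])


# ---------------------------------------------------------------------------
# severity assignment and feature derivation


def assign_cc_level(record: InpatientRecord, table: CCTable) -> CCLevel:
    """Severity of an admission from its secondary diagnoses.

    MCC if any secondary diagnosis is on the MCC inclusion list and the
    primary diagnosis is not on that code's exclusion list; else CC by the
    same rule; else Non-CC.  MCC takes precedence over CC, and the result
    does not depend on the order of the secondary diagnoses.
    """
    primary = record.primary_dx
    for codes, level in ((table.mcc_codes, CCLevel.MCC), (table.cc_codes, CCLevel.CC)):
        for sec in record.secondary_dx:
            if sec in codes and primary not in table.excluded_primaries(sec):
                return level
    return CCLevel.NON_CC


def age_band_of(age: int) -> str:
    """Age band with inclusive upper bounds 17 and 65 (0-17, 18-65, >65)."""
    if age <= _AGE_BAND_EDGES[0]:
        return AGE_BANDS[0]
    if age <= _AGE_BAND_EDGES[1]:
        return AGE_BANDS[1]
    return AGE_BANDS[2]


def derive_features(record: InpatientRecord, table: CCTable) -> DerivedFeatures:
    """Age band, long-stay indicator (LOS > 30 days) and CC level."""
    return DerivedFeatures(
        age_band=age_band_of(record.age),
        long_stay=record.los > 30,
        cc_level=assign_cc_level(record, table),
    )


# ---------------------------------------------------------------------------
# exclusion criteria


def apply_exclusions(
    records: Sequence[InpatientRecord],
    scheme_codes: frozenset[str] | set[str],
    los_max: int = 60,
    trim: tuple[float, float] | None = (1.0, 99.0),
    component_tol: float = COMPONENT_SUM_TOL,
) -> tuple[list[InpatientRecord], ExclusionLog]:
    """Apply the four exclusion criteria in order and account for every record.

    Order: (1) missing or invalid items; (2) principal diagnosis, or first
    listed procedure, not in ``scheme_codes``; (3) LOS > ``los_max``;
    (4) total cost strictly below the low or strictly above the high
    percentile bound, with the bounds computed (linear interpolation) on the
    cohort surviving criteria 1-3.  A record violating several criteria is
    counted only under the first.  ``trim=None`` disables criterion 4 (for
    cohorts that have already been percentile-trimmed).
    """
    if trim is not None:
        low, high = trim
        if not (0 <= low < high <= 100):
            raise ConfigurationError(f"invalid trim percentiles: {trim}")
    counts = dict.fromkeys(ExclusionLog.CRITERIA, 0)
    survivors: list[InpatientRecord] = []
    for r in records:
        if r.missing_fields() or r.problems(component_tol):
            counts["missing_fields"] += 1
        elif r.primary_dx not in scheme_codes or (
            r.procedures and r.procedures[0] not in scheme_codes
        ):
            counts["code_not_in_scheme"] += 1
        elif r.los > los_max:
            counts["los_gt_60"] += 1
        else:
            survivors.append(r)
    if not survivors:
        raise PipelineError("no records survive criteria 1-3; nothing to trim")
    if trim is None:
        retained = survivors
    else:
        costs = np.array([r.total_cost for r in survivors])
        lo_bound, hi_bound = np.percentile(costs, [low, high])
        retained = [
            r for r in survivors if lo_bound <= r.total_cost <= hi_bound
        ]
    counts["cost_percentile_trim"] = len(survivors) - len(retained)
    log = ExclusionLog(
        input_n=len(records), counts=counts, retained_n=len(retained)
    )
    log.check()
    return retained, log


# ---------------------------------------------------------------------------
# analysis container


def cohort_frame(
    records: Sequence[InpatientRecord], table: CCTable
) -> pd.DataFrame:
    """Cleaned cohort as the tabular analysis container, with derived
    features (``age_band``, ``long_stay``, ``cc_level``) appended."""
    rows = []
    for r in records:
        feats = derive_features(r, table)
        row = {
            "record_id": r.record_id,
            "sex": r.sex,
            "age": r.age,
            "age_band": feats.age_band,
            "allergy": r.allergy,
            "social_insurance": r.social_insurance,
            "admission_route": r.admission_route,
            "discharge_mode": r.discharge_mode,
            "admission_year": r.admission_year,
            "los": r.los,
            "long_stay": feats.long_stay,
            "cc_level": feats.cc_level.value,
            "total_cost": r.total_cost,
        }
        for c in COST_COMPONENTS:
            row[f"cost_{c}"] = r.cost_components[c]
        rows.append(row)
    return pd.DataFrame(rows)
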