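"""Data model for Individual Case Safety Reports (ICSRs).

A spontaneous pharmacovigilance report carries the patient's demographics
(age, sex), administrative context (country, reporter qualification), the
drugs administered with their characterization role (suspect, interacting or
concomitant), the adverse reactions coded as MedDRA-style preferred terms
(PTs), a regulatory seriousness flag with its criteria, and the outcome at
the time of reporting.

Only the fields an age-stratified case/non-case disproportionality analysis
consumes are modelled.  Drug names and PTs are canonicalized on ingest
(whitespace-collapsed, case-folded); matching downstream is exact string
equality — no dictionary hierarchy is applied.  ``sex``, ``country``,
``reporter_qualification`` and ``outcome`` admit an explicit ``"unknown"``
value because spontaneous-report databases tabulate unknowns as their own
category; age is mandatory because every analysis here is age-stratified.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal

from pydantic import BaseModel, ConfigDict, Field, field_validator

AgeUnit = Literal["days", "months", "years"]
Sex = Literal["female", "male", "unknown"]
ReporterQualification = Literal[
    "physician",
    "pharmacist",
    "other_health_professional",
    "lawyer",
    "consumer",
    "unknown",
]
DrugRole = Literal["suspect", "interacting", "concomitant"]
SeriousnessCriterion = Literal[
    "hospitalization",
    "congenital_anomaly",
    "disability",
    "life_threatening",
    "death",
    "other_medically_important",
]
Outcome = Literal[
    "recovered",
    "recovering",
    "recovered_with_sequelae",
    "not_recovered",
    "fatal",
    "unknown",
]

#: Reporter qualifications counted as healthcare professionals in the
#: sensitivity analysis.
HCP_QUALIFICATIONS = frozenset({"physician", "pharmacist", "other_health_professional"})

#: Drug roles attributed to a case by default: suspected-or-interacting drugs
#: are the reported associations; concomitants are background medication.
DEFAULT_CASE_ROLES = frozenset({"suspect", "interacting"})


def canonicalize(term: str) -> str:
    """Canonical form of a drug name or PT: trimmed, internal whitespace
    collapsed to single spaces, case-folded.  Idempotent."""
    return " ".join(str(term).split()).casefold()


class DrugEntry(BaseModel):
    """One drug on a report, with its characterization role."""

    model_config = ConfigDict(frozen=True)

    drug_name: str
    role: DrugRole = "suspect"

    @field_validator("drug_name")
    @classmethod
    def _canon(cls, v: str) -> str:
        return canonicalize(v)


class IcsrReport(BaseModel):
    """One spontaneous report: demographics, drugs, reactions, seriousness."""

    report_id: str
    age_value: float
    age_unit: AgeUnit
    sex: Sex = "unknown"
    country: str = "unknown"
    reporter_qualification: ReporterQualification = "unknown"
    drugs: list[DrugEntry]
    reactions: frozenset[str]
    serious: bool = False
    seriousness_criteria: frozenset[SeriousnessCriterion] = frozenset()
    outcome: Outcome = "unknown"

    @field_validator("reactions")
    @classmethod
    def _canon_reactions(cls, v: frozenset[str]) -> frozenset[str]:
        return frozenset(canonicalize(pt) for pt in v)

    @field_validator("country")
    @classmethod
    def _trim_country(cls, v: str) -> str:
        return v.strip()


class PtQuery(BaseModel):
    """A named set of preferred terms defining a reaction query."""

    model_config = ConfigDict(frozen=True)

    name: str
    pts: frozenset[str] = Field(min_length=1)

    @field_validator("pts")
    @classmethod
    def _canon_pts(cls, v: frozenset[str]) -> frozenset[str]:
        return frozenset(canonicalize(pt) for pt in v)


class ReportSet(BaseModel):
    """An ordered collection of reports with unique identifiers."""

    reports: list[IcsrReport]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):  # type: ignore[override]
        return iter(self.reports)


def validate_report(r: IcsrReport) -> list[str]:
    """Return the list of invariant violations for a report.

    An empty list means the report is internally consistent.  Violations are
    returned, not raised, so callers can aggregate them (e.g. the reader
    names the offending line).
    """
    violations: list[str] = []
    if not r.reactions:
        violations.append("reactions: must contain at least one preferred term")
    if not r.drugs:
        violations.append("drugs: must contain at least one drug entry")
    for i, d in enumerate(r.drugs):
        if not d.drug_name:
            violations.append(f"drugs[{i}].drug_name: must be non-empty")
    if r.serious and not r.seriousness_criteria:
        violations.append("serious: true requires non-empty seriousness_criteria")
    if not r.serious and r.seriousness_criteria:
        violations.append("seriousness_criteria: non-empty requires serious=true")
    if r.outcome == "fatal" and "death" not in r.seriousness_criteria:
        violations.append("outcome: fatal requires 'death' in seriousness_criteria")
    if not math.isfinite(r.age_value):
        violations.append("age_value: must be finite")
    elif r.age_value < 0:
        violations.append("age_value: must be non-negative")
    return violations


def validate_report_set(rs: ReportSet) -> list[str]:
    """Validate every report and the uniqueness of report identifiers."""
    violations: list[str] = []
    seen: set[str] = set()
    for r in rs.reports:
        if r.report_id in seen:
            violations.append(f"report_id: duplicate '{r.report_id}'")
        seen.add(r.report_id)
        violations.extend(f"{r.report_id}: {v}" for v in validate_report(r))
    return violations


def make_report(
    report_id: str,
    age_value: float,
    age_unit: AgeUnit,
    drugs: Iterable[tuple[str, DrugRole]] | Iterable[str],
    reactions: Iterable[str],
    **kwargs,
) -> IcsrReport:
    """Convenience constructor used heavily in tests and examples.

    ``drugs`` accepts plain names (role defaults to suspect) or
    ``(name, role)`` pairs.
    """
    entries = []
    for d in drugs:
        if isinstance(d, str):
            entries.append(DrugEntry(drug_name=d))
        else:
            name, role = d
            entries.append(DrugEntry(drug_name=name, role=role))
    return IcsrReport(
        report_id=report_id,
        age_value=age_value,
        age_unit=age_unit,
        drugs=entries,
        reactions=frozenset(reactions),
        **kwargs,
    )
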