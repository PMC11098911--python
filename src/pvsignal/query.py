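"""Cohort query layer: age banding, case selection, co-reporting tables.

Pediatric reports are stratified into three half-open age bands measured in
months — infants [0, 24), children [24, 144), adolescents [144, 216) — which
partition the under-18 range without gap or overlap.  Case selection is by
intersection of a report's reaction PTs with a named PT query, optionally
restricted to one band; all ranked outputs break count ties alphabetically
so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .icsr import DEFAULT_CASE_ROLES, IcsrReport, PtQuery, ReportSet
from .rounding import percentage

#: Average Gregorian month length in days, used for day->month conversion.
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lo, hi) in months."""

    label: str
    lo: float
    hi: float

    def contains(self, months: float) -> bool:
        return self.lo <= months < self.hi


INFANT = AgeBand("infant", 0.0, 24.0)
CHILD = AgeBand("child", 24.0, 144.0)
ADOLESCENT = AgeBand("adolescent", 144.0, 216.0)
ALL_PEDIATRIC = AgeBand("all_pediatric", 0.0, 216.0)

PEDIATRIC_BANDS: tuple[AgeBand, ...] = (INFANT, CHILD, ADOLESCENT)
BANDS_BY_LABEL = {b.label: b for b in (*PEDIATRIC_BANDS, ALL_PEDIATRIC)}
# accepted spelling variants on CLI / config surfaces
BANDS_BY_LABEL["all-pediatric"] = ALL_PEDIATRIC
BANDS_BY_LABEL["all"] = ALL_PEDIATRIC

BandLike = Union[AgeBand, str]


def resolve_band(band: BandLike) -> AgeBand:
    if isinstance(band, AgeBand):
        return band
    try:
        return BANDS_BY_LABEL[band]
    except KeyError:
        raise ValueError(
            f"unknown age band {band!r}; expected one of "
            f"{sorted(set(BANDS_BY_LABEL))}"
        ) from None


def age_in_months(age_value: float, age_unit: str) -> float:
    """Normalize a recorded age to months."""
    if age_value < 0:
        raise ValueError("age_value must be non-negative")
    if age_unit == "days":
        return age_value / DAYS_PER_MONTH
    if age_unit == "months":
        return float(age_value)
    if age_unit == "years":
        return age_value * 12.0
    raise ValueError(f"unknown age unit: {age_unit!r}")


def classify_age_band(r: IcsrReport) -> str:
    """Band label for a report: infant / child / adolescent / out_of_scope."""
    months = age_in_months(r.age_value, r.age_unit)
    for band in PEDIATRIC_BANDS:
        if band.contains(months):
            return band.label
    return "out_of_scope"


def report_in_band(r: IcsrReport, band: BandLike) -> bool:
    return resolve_band(band).contains(age_in_months(r.age_value, r.age_unit))


@dataclass
class CaseSet:
    """Reports matching a PT query within an age band (the 'cases')."""

    query: PtQuery
    band: AgeBand
    cases: list[IcsrReport] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def select_cases(rs: ReportSet, q: PtQuery, band: BandLike = ALL_PEDIATRIC) -> CaseSet:
    """All reports whose reactions intersect ``q.pts`` within ``band``.

    Input order is preserved.
    """
    band = resolve_band(band)
    cases = [r for r in rs if (r.reactions & q.pts) and report_in_band(r, band)]
    return CaseSet(query=q, band=band, cases=cases)


def co_occurrence_cases(
    rs: ReportSet, q1: PtQuery, q2: PtQuery, band: BandLike = ALL_PEDIATRIC
) -> CaseSet:
    """Reports featuring PTs from both queries within the band.

    Used to intersect the primary catatonia query with feature terms such as
    agitation or speech disorder.  The result is labelled ``q1 & q2`` and is
    a subset of ``select_cases(rs, q1, band)``.
    """
    band = resolve_band(band)
    cases = [
        r
        for r in rs
        if (r.reactions & q1.pts)
        and (r.reactions & q2.pts)
        and report_in_band(r, band)
    ]
    combined = PtQuery(name=f"{q1.name} & {q2.name}", pts=q1.pts | q2.pts)
    return CaseSet(query=combined, band=band, cases=cases)


def filter_by_reporter(cs: CaseSet, qualifications: Iterable[str]) -> CaseSet:
    """Retain cases whose reporter qualification is in ``qualifications``."""
    quals = frozenset(qualifications)
    return CaseSet(
        query=cs.query,
        band=cs.band,
        cases=[r for r in cs.cases if r.reporter_qualification in quals],
    )


def filter_report_set_by_reporter(rs: ReportSet, qualifications: Iterable[str]) -> ReportSet:
    """Report-set level reporter filter (used by the sensitivity rerun)."""
    quals = frozenset(qualifications)
    return ReportSet(
        reports=[r for r in rs if r.reporter_qualification in quals],
        provenance=f"{rs.provenance} [reporters: {','.join(sorted(quals))}]",
    )


def _ranked(counts: dict[str, int], denominator: int) -> list[tuple[str, int, float]]:
    """Sort by count descending, ties alphabetical; attach percentages."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, n, percentage(n, denominator)) for name, n in ordered]


def co_reported_pt_counts(
    cs: CaseSet, exclude: PtQuery | None = None
) -> list[tuple[str, int, float]]:
    """Ranked (PT, case count, % of cases) over PTs co-reported with the query.

    The query's own PTs (or ``exclude.pts`` when given) are omitted; the
    percentage denominator is the number of cases.
    """
    if len(cs) == 0:
        raise ValueError("co_reported_pt_counts: empty case set (percentages undefined)")
    excluded = exclude.pts if exclude is not None else cs.query.pts
    counts: dict[str, int] = {}
    for r in cs:
        for pt in r.reactions - excluded:
            counts[pt] = counts.get(pt, 0) + 1
    return _ranked(counts, len(cs))


def drug_case_counts(
    cs: CaseSet, roles: Iterable[str] = DEFAULT_CASE_ROLES
) -> list[tuple[str, int, float]]:
    """Ranked (drug, case count, % of cases) with set semantics per report.

    A drug listed twice on one report counts once; only entries whose role is
    in ``roles`` (default: suspect or interacting) attribute the case.
    """
    if len(cs) == 0:
        raise ValueError("drug_case_counts: empty case set (percentages undefined)")
    roles = frozenset(roles)
    counts: dict[str, int] = {}
    for r in cs:
        names = {d.drug_name for d in r.drugs if d.role in roles}
        for name in names:
            counts[name] = counts.get(name, 0) + 1
    return _ranked(counts, len(cs))
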