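"""Case/non-case disproportionality statistics: ROR and information component.

For a drug D and a reaction query Q within one stratum, reports are
cross-classified into the 2x2 table

    ============  =========  ============
                  Q present  Q absent
    D present         a          b
    D absent          c          d
    ============  =========  ============

The reporting odds ratio ``ROR = (a*d)/(b*c)`` compares the odds of exposure
to D among cases (reports with Q) and non-cases.  Its 95% confidence
interval uses the Woolf log-normal approximation
``exp(ln ROR +/- z*sqrt(1/a+1/b+1/c+1/d))``; if any cell is zero the
Haldane–Anscombe correction adds 0.5 to all four cells (flagged via
``corrected``).

The information component is the shrinkage-regularized observed/expected
log-ratio used for first-pass screening of large spontaneous-report
databases:

    IC     = log2((O + 0.5) / (E + 0.5)),  O = a,  E = (a+b)(a+c)/N
    IC_025 = IC - 3.3*(O+0.5)^(-1/2) - 2*(O+0.5)^(-3/2)

where IC_025 is a closed-form approximation to the 2.5% quantile of the
posterior credibility interval; :func:`ic025_exact` evaluates the exact
gamma-quantile form ``log2(q_gamma(0.025; shape=O+0.5, rate=E+0.5))`` for
cross-checking.  The additive +0.5 shrinkage pulls small-count pairs toward
IC = 0 and is what keeps the screen conservative when expected counts are
tiny.

A drug–reaction pair is declared a signal when all three hold:
at least ``min_cases`` cases with the drug, IC_025 > 0, and the ROR 95% CI
lower bound above 1.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .icsr import DEFAULT_CASE_ROLES, PtQuery, ReportSet
from .query import BandLike, resolve_band, report_in_band
from .rounding import percentage

DEFAULT_MIN_CASES = 5
Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case/non-case table for one drug x PT-query x stratum."""

    a: int
    b: int
    c: int
    d: int
    stratum: str = ""
    drug_name: str = ""
    query_name: str = ""

    def __post_init__(self) -> None:
        for cell, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or v != int(v):
                raise ValueError(f"cell {cell} must be a non-negative integer, got {v}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    low: float
    high: float
    corrected: bool


def compute_ror(t: ContingencyTable, z: float = Z_95) -> RorResult:
    """ROR with Woolf 95% CI; Haldane–Anscombe +0.5 on any zero cell."""
    if t.a + t.c == 0:
        raise ValueError(
            "ROR undefined: the query PT does not occur in the stratum (a = c = 0)"
        )
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    return RorResult(
        ror=ror,
        low=math.exp(log_ror - z * se),
        high=math.exp(log_ror + z * se),
        corrected=corrected,
    )


def compute_ic(t: ContingencyTable) -> tuple[float, float]:
    """Information component and its IC_025 credibility lower bound."""
    n = t.N
    if n == 0:
        raise ValueError("IC undefined for an empty stratum (N = 0)")
    o = float(t.a)
    e = (t.a + t.b) * (t.a + t.c) / n
    ic = math.log2((o + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (o + 0.5) ** -0.5 - 2.0 * (o + 0.5) ** -1.5
    return ic, ic025


def ic025_exact(t: ContingencyTable) -> float:
    """Exact 2.5% credibility quantile of the IC (gamma posterior).

    ``log2`` of the 0.025 quantile of a Gamma(shape = O + 0.5,
    rate = E + 0.5) distribution.  Used as an independent cross-check of the
    closed-form approximation in :func:`compute_ic`.
    """
    n = t.N
    if n == 0:
        raise ValueError("IC undefined for an empty stratum (N = 0)")
    o = float(t.a)
    e = (t.a + t.b) * (t.a + t.c) / n
    q = _sps.gamma.ppf(0.025, a=o + 0.5, scale=1.0 / (e + 0.5))
    return float(np.log2(q))


def evaluate_signal(
    n_cases: int,
    ic025: float,
    ror_low: float,
    min_cases: int = DEFAULT_MIN_CASES,
) -> bool:
    """Dual signal criterion: enough cases, IC_025 > 0 and ROR CI low > 1."""
    return n_cases >= min_cases and ic025 > 0.0 and ror_low > 1.0


@dataclass(frozen=True)
class DisproStats:
    """Full disproportionality result for one drug within one scan."""

    drug_name: str
    n_cases: int
    pct_of_cases: float
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic025: float
    corrected: bool
    is_signal: bool


@dataclass
class SignalTable:
    """Scan output: one row per drug with at least ``min_cases`` cases."""

    rows: list[DisproStats]
    stratum: str
    query_name: str
    min_cases: int
    roles: frozenset[str]
    background: str


def _case_drug_names(report, roles: frozenset[str]) -> set[str]:
    return {d.drug_name for d in report.drugs if d.role in roles}


def build_contingency(
    rs: ReportSet,
    drug: str,
    q: PtQuery,
    band: BandLike,
    roles: Iterable[str] = DEFAULT_CASE_ROLES,
    background: str = "stratum",
) -> ContingencyTable:
    """Cross-classify reports for one drug against one PT query.

    ``background`` selects the comparator population: ``"stratum"`` draws
    non-cases from the same age band as the cases (the conservative default
    for age-stratified scans), ``"global"`` draws them from the whole
    database regardless of age (cases remain band-restricted; query-positive
    reports outside the band belong to neither group).
    """
    band_r = resolve_band(band)
    roles = frozenset(roles)
    a = b = c = d = 0
    for r in rs:
        is_case_pt = bool(r.reactions & q.pts)
        in_band = report_in_band(r, band_r)
        if background == "stratum":
            if not in_band:
                continue
            is_case = is_case_pt
        elif background == "global":
            if is_case_pt and not in_band:
                continue  # neither case nor comparator
            is_case = is_case_pt and in_band
        else:
            raise ValueError(f"unknown background mode: {background!r}")
        has_drug = drug in _case_drug_names(r, roles)
        if is_case:
            a += has_drug
            c += not has_drug
        else:
            b += has_drug
            d += not has_drug
    return ContingencyTable(
        a=a, b=b, c=c, d=d, stratum=band_r.label, drug_name=drug, query_name=q.name
    )


def _stats_from_table(t: ContingencyTable, n_total_cases: int, min_cases: int) -> DisproStats:
    ror = compute_ror(t)
    ic, ic025 = compute_ic(t)
    return DisproStats(
        drug_name=t.drug_name,
        n_cases=t.a,
        pct_of_cases=percentage(t.a, n_total_cases),
        ror=ror.ror,
        ror_low=ror.low,
        ror_high=ror.high,
        ic=ic,
        ic025=ic025,
        corrected=ror.corrected,
        is_signal=evaluate_signal(t.a, ic025, ror.low, min_cases),
    )


def run_signal_scan(
    rs: ReportSet,
    q: PtQuery,
    band: BandLike,
    roles: Iterable[str] = DEFAULT_CASE_ROLES,
    min_cases: int = DEFAULT_MIN_CASES,
    background: str = "stratum",
) -> SignalTable:
    """Scan every drug with at least ``min_cases`` cases in the band.

    Rows (including non-signals) are sorted by case count descending, ties
    alphabetical, so the table is deterministic and order-independent of the
    input report order.
    """
    band_r = resolve_band(band)
    roles = frozenset(roles)
    if background not in ("stratum", "global"):
        raise ValueError(f"unknown background mode: {background!r}")

    case_counts: Counter[str] = Counter()
    universe_counts: Counter[str] = Counter()
    n_cases = 0
    n_universe = 0
    for r in rs:
        is_case_pt = bool(r.reactions & q.pts)
        in_band = report_in_band(r, band_r)
        if background == "stratum":
            if not in_band:
                continue
            is_case = is_case_pt
        else:
            if is_case_pt and not in_band:
                continue
            is_case = is_case_pt and in_band
        names = _case_drug_names(r, roles)
        n_universe += 1
        universe_counts.update(names)
        if is_case:
            n_cases += 1
            case_counts.update(names)

    rows: list[DisproStats] = []
    for drug, a in case_counts.items():
        if a < min_cases:
            continue
        b = universe_counts[drug] - a
        c = n_cases - a
        d = n_universe - a - b - c
        t = ContingencyTable(
            a=a, b=b, c=c, d=d,
            stratum=band_r.label, drug_name=drug, query_name=q.name,
        )
        rows.append(_stats_from_table(t, n_cases, min_cases))
    rows.sort(key=lambda s: (-s.n_cases, s.drug_name))
    return SignalTable(
        rows=rows,
        stratum=band_r.label,
        query_name=q.name,
        min_cases=min_cases,
        roles=roles,
        background="stratum" if background == "stratum" else "global",
    )


def scan_all_single_pts(
    rs: ReportSet,
    pts: Sequence[str],
    bands: Sequence[BandLike],
    roles: Iterable[str] = DEFAULT_CASE_ROLES,
    min_cases: int = DEFAULT_MIN_CASES,
) -> list[tuple[str, str, DisproStats]]:
    """Scan every drug x single-PT pair across several bands at once.

    Equivalent to running :func:`run_signal_scan` with a one-PT query for
    each PT in ``pts`` within each band (stratum background), but counts all
    pairs in one vectorized pass — used by the null-calibration and
    recovery simulation studies where hundreds of full-database scans are
    needed.  Returns ``(band label, pt, stats)`` tuples for qualifying pairs.
    """
    roles = frozenset(roles)
    bands_r = [resolve_band(b) for b in bands]
    pt_index = {pt: j for j, pt in enumerate(pts)}
    drug_names = sorted({d.drug_name for r in rs for d in r.drugs if d.role in roles})
    drug_index = {name: i for i, name in enumerate(drug_names)}

    n = len(rs)
    months = np.empty(n)
    presence = np.zeros((n, len(drug_names)), dtype=bool)
    reactions = np.zeros((n, len(pts)), dtype=bool)
    from .query import age_in_months  # local to avoid cycle at import time

    for i, r in enumerate(rs):
        months[i] = age_in_months(r.age_value, r.age_unit)
        for d in r.drugs:
            if d.role in roles:
                presence[i, drug_index[d.drug_name]] = True
        for pt in r.reactions:
            j = pt_index.get(pt)
            if j is not None:
                reactions[i, j] = True

    out: list[tuple[str, str, DisproStats]] = []
    for band in bands_r:
        mask = (months >= band.lo) & (months < band.hi)
        pres_b = presence[mask]
        reac_b = reactions[mask]
        n_band = int(mask.sum())
        if n_band == 0:
            continue
        a_mat = pres_b.T.astype(np.int64) @ reac_b.astype(np.int64)
        drug_tot = pres_b.sum(axis=0)
        pt_tot = reac_b.sum(axis=0)
        qual_i, qual_j = np.nonzero(a_mat >= min_cases)
        for i, j in zip(qual_i.tolist(), qual_j.tolist()):
            a = int(a_mat[i, j])
            b = int(drug_tot[i]) - a
            c = int(pt_tot[j]) - a
            d = n_band - a - b - c
            t = ContingencyTable(
                a=a, b=b, c=c, d=d,
                stratum=band.label, drug_name=drug_names[i], query_name=pts[j],
            )
            out.append(
                (band.label, pts[j], _stats_from_table(t, int(pt_tot[j]), min_cases))
            )
    return out
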