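"""Descriptive cohort tables and the end-to-end analysis pipeline.

Reproduces the descriptive layer of an age-stratified spontaneous-report
cohort study: a characteristics table (sex / country / reporter
qualification per band with column percentages), age mean +/- sample SD per
band, seriousness and outcome summaries with explicit denominators, ranked
top-drug tables, catatonia-feature distributions, co-occurrence counts, and
a healthcare-professional (HCP) sensitivity rerun of the signal scans.

Every percentage printed anywhere goes through
:func:`pvsignal.rounding.percentage` (round half-up, one decimal), so each
printed cell recomputes exactly from its printed numerator and denominator.
The pipeline writes TSV tables with a header comment carrying the config
hash and seed, and is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field

from .dispro import DEFAULT_MIN_CASES, SignalTable, run_signal_scan
from .icsr import HCP_QUALIFICATIONS, PtQuery, ReportSet
from .io import read_pt_queries, read_report_set, write_report_set
from .query import (
    ALL_PEDIATRIC,
    PEDIATRIC_BANDS,
    CaseSet,
    classify_age_band,
    co_occurrence_cases,
    co_reported_pt_counts,
    drug_case_counts,
    filter_report_set_by_reporter,
    resolve_band,
    select_cases,
)
from .rounding import percentage

logger = logging.getLogger("pvsignal.pipeline")

PRIMARY_PT = "catatonia"
FEATURE_PTS = (
    "malignant catatonia",
    "withdrawal catatonia",
    "automatism",
    "echolalia",
    "echopraxia",
    "posturing",
    "waxy flexibility",
)
CO_OCCURRENCE_PTS = (
    "agitation",
    "eating disorder",
    "speech disorder",
    "stereotypy",
    "social avoidant behaviour",
)
SENSITIVITY_PTS = (
    "catatonia",
    "automatism",
    "echolalia",
    "echopraxia",
    "posturing",
    "waxy flexibility",
)


def default_pt_queries() -> dict[str, PtQuery]:
    """One single-PT query per analysed preferred term."""
    names = {PRIMARY_PT, *FEATURE_PTS, *CO_OCCURRENCE_PTS, *SENSITIVITY_PTS}
    return {name: PtQuery(name=name, pts=frozenset({name})) for name in sorted(names)}


@dataclass
class OutcomeSummary:
    """Outcome distribution among reports with a known outcome."""

    n_cases: int
    known_n: int
    pct_known_of_cases: float
    distribution: list[tuple[str, int, float]]  # (outcome, n, % of known)
    recovered_or_recovering: tuple[int, float]  # combined row


def outcome_summary(cs: CaseSet) -> OutcomeSummary:
    """Summarize outcomes; percentages use the known-outcome denominator."""
    known = [r.outcome for r in cs if r.outcome != "unknown"]
    n_known = len(known)
    if n_known == 0:
        return OutcomeSummary(
            n_cases=len(cs),
            known_n=0,
            pct_known_of_cases=0.0 if len(cs) == 0 else percentage(0, len(cs)),
            distribution=[],
            recovered_or_recovering=(0, 0.0),
        )
    counts: dict[str, int] = {}
    for o in known:
        counts[o] = counts.get(o, 0) + 1
    dist = [
        (o, n, percentage(n, n_known))
        for o, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    combined = counts.get("recovered", 0) + counts.get("recovering", 0)
    return OutcomeSummary(
        n_cases=len(cs),
        known_n=n_known,
        pct_known_of_cases=percentage(n_known, len(cs)) if len(cs) else 0.0,
        distribution=dist,
        recovered_or_recovering=(combined, percentage(combined, n_known)),
    )


@dataclass
class CohortSummary:
    """Structure of a cohort characteristics table.

    ``categorical`` maps block name (sex, country, reporter_qualification)
    to category to band label to ``(count, % of the band's case total)``.
    Age statistics are reported in months for infants and years otherwise,
    with the sample SD (n-1 denominator).
    """

    query_name: str
    totals: dict[str, int]
    categorical: dict[str, dict[str, dict[str, tuple[int, float]]]]
    age_stats: dict[str, tuple[int, float, float, str]]  # n, mean, sd, unit
    seriousness: dict[str, dict[str, int | float]]
    outcomes: dict[str, OutcomeSummary]
    top_drugs: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)


_BAND_AGE_UNIT = {"infant": "months", "child": "years", "adolescent": "years",
                  "all_pediatric": "years"}


def _age_in_band_unit(r, band_label: str) -> float:
    from .query import age_in_months

    months = age_in_months(r.age_value, r.age_unit)
    return months if _BAND_AGE_UNIT[band_label] == "months" else months / 12.0


def cohort_characteristics(rs: ReportSet, q: PtQuery) -> CohortSummary:
    """Characteristics of the pediatric case cohort for query ``q``.

    Columns are the three pediatric bands plus the all-pediatric total; each
    categorical cell carries the count and the percentage of that column's
    case total.
    """
    band_labels = [b.label for b in PEDIATRIC_BANDS] + [ALL_PEDIATRIC.label]
    case_sets = {lbl: select_cases(rs, q, lbl) for lbl in band_labels}
    if len(case_sets[ALL_PEDIATRIC.label]) == 0:
        raise ValueError(f"cohort_characteristics: no pediatric cases for {q.name!r}")
    totals = {lbl: len(cs) for lbl, cs in case_sets.items()}

    def block(getter) -> dict[str, dict[str, tuple[int, float]]]:
        out: dict[str, dict[str, tuple[int, float]]] = {}
        for lbl, cs in case_sets.items():
            if totals[lbl] == 0:
                continue
            counts: dict[str, int] = {}
            for r in cs:
                counts[getter(r)] = counts.get(getter(r), 0) + 1
            for cat, n in counts.items():
                out.setdefault(cat, {})[lbl] = (n, percentage(n, totals[lbl]))
        return out

    categorical = {
        "sex": block(lambda r: r.sex),
        "country": block(lambda r: r.country),
        "reporter_qualification": block(lambda r: r.reporter_qualification),
    }

    age_stats: dict[str, tuple[int, float, float, str]] = {}
    for lbl, cs in case_sets.items():
        if totals[lbl] == 0:
            continue
        ages = np.asarray([_age_in_band_unit(r, lbl) for r in cs])
        sd = float(np.std(ages, ddof=1)) if len(ages) > 1 else float("nan")
        age_stats[lbl] = (len(ages), float(np.mean(ages)), sd, _BAND_AGE_UNIT[lbl])

    seriousness: dict[str, dict[str, int | float]] = {}
    for lbl, cs in case_sets.items():
        if totals[lbl] == 0:
            continue
        n_serious = sum(r.serious for r in cs)
        n_death = sum(r.outcome == "fatal" for r in cs)
        seriousness[lbl] = {
            "n_cases": totals[lbl],
            "n_serious": n_serious,
            "pct_serious": percentage(n_serious, totals[lbl]),
            "n_death": n_death,
            "pct_death": percentage(n_death, totals[lbl]),
        }

    outcomes = {
        lbl: outcome_summary(cs) for lbl, cs in case_sets.items() if totals[lbl] > 0
    }
    top_drugs = {
        lbl: drug_case_counts(cs) for lbl, cs in case_sets.items() if totals[lbl] > 0
    }
    return CohortSummary(
        query_name=q.name,
        totals=totals,
        categorical=categorical,
        age_stats=age_stats,
        seriousness=seriousness,
        outcomes=outcomes,
        top_drugs=top_drugs,
    )


def feature_distribution(
    rs: ReportSet, feature_queries: Sequence[PtQuery], band
) -> list[tuple[str, int]]:
    """Case count per feature query within a band, in the given order."""
    if not feature_queries:
        raise ValueError("feature_distribution: no feature queries given")
    return [(q.name, len(select_cases(rs, q, band))) for q in feature_queries]


class PipelineConfig(BaseModel):
    """Configuration of the end-to-end analysis pipeline.

    When ``reports`` is null the pipeline simulates a default pediatric
    database at ``simulate_scale`` with ``seed``.  PT queries default to one
    single-PT query per analysed term when no query file is given.
    """

    reports: Optional[str] = None
    simulate_scale: int = Field(default=1, ge=1)
    simulate_n: Optional[int] = Field(default=None, ge=1,
                                      description="Override the simulated report count")
    seed: int = 0
    pt_queries: Optional[str] = None
    primary: str = PRIMARY_PT
    features: list[str] = Field(default_factory=lambda: list(FEATURE_PTS))
    co_occurrence: list[str] = Field(default_factory=lambda: list(CO_OCCURRENCE_PTS))
    sensitivity: list[str] = Field(default_factory=lambda: list(SENSITIVITY_PTS))
    bands: list[str] = Field(default_factory=lambda: ["infant", "child", "adolescent"])
    min_cases: int = Field(default=DEFAULT_MIN_CASES, ge=1)
    roles: list[str] = Field(default_factory=lambda: ["suspect", "interacting"])
    background: str = "stratum"
    hcp_qualifications: list[str] = Field(
        default_factory=lambda: sorted(HCP_QUALIFICATIONS)
    )
    outdir: str = "pvsignal_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"outdir", "log_level"})
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# TSV emission


def _fmt(x) -> str:
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        if x != x:  # nan
            return "na"
        return f"{x:.1f}" if abs(x) < 1e6 else f"{x:.4g}"
    return str(x)


def _fmt3(x: float) -> str:
    return "na" if x != x else f"{x:.3f}"


def _write_tsv(path: Path, header: list[str], rows: list[list], stamp: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {stamp}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_signal_table_tsv(table: SignalTable, path: Path, stamp: str) -> None:
    header = [
        "drug", "n", "pct_of_cases", "ror", "ror_low", "ror_high",
        "ic", "ic025", "corrected", "is_signal",
    ]
    rows = [
        [
            s.drug_name, s.n_cases, s.pct_of_cases,
            _fmt3(s.ror), _fmt3(s.ror_low), _fmt3(s.ror_high),
            _fmt3(s.ic), _fmt3(s.ic025), s.corrected, s.is_signal,
        ]
        for s in table.rows
    ]
    _write_tsv(path, header, rows, stamp)


# ---------------------------------------------------------------------------
# pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _load_queries(cfg: PipelineConfig) -> dict[str, PtQuery]:
    queries = (
        read_pt_queries(cfg.pt_queries) if cfg.pt_queries else default_pt_queries()
    )
    needed = {cfg.primary, *cfg.features, *cfg.co_occurrence, *cfg.sensitivity}
    for name in sorted(needed):
        if name not in queries:
            queries[name] = PtQuery(name=name, pts=frozenset({name}))
    return queries


def _write_cohort_tables(summary: CohortSummary, outdir: Path, stamp: str) -> None:
    band_labels = [b.label for b in PEDIATRIC_BANDS] + [ALL_PEDIATRIC.label]
    rows: list[list] = []
    rows.append(
        ["total", "total"]
        + [v for lbl in band_labels for v in (summary.totals.get(lbl, 0), 100.0)]
    )
    for blockname, block in summary.categorical.items():
        for cat in sorted(block):
            cells = []
            for lbl in band_labels:
                n, pct = block[cat].get(lbl, (0, 0.0))
                cells += [n, pct]
            rows.append([blockname, cat] + cells)
    header = ["block", "category"] + [
        f"{lbl}_{suffix}" for lbl in band_labels for suffix in ("n", "pct")
    ]
    _write_tsv(outdir / "cohort_characteristics.tsv", header, rows, stamp)

    age_rows = [
        [lbl, *summary.age_stats[lbl][:1],
         _fmt(summary.age_stats[lbl][1]), _fmt(summary.age_stats[lbl][2]),
         summary.age_stats[lbl][3]]
        for lbl in band_labels
        if lbl in summary.age_stats
    ]
    _write_tsv(outdir / "age_stats.tsv", ["band", "n", "mean", "sd", "unit"],
               age_rows, stamp)

    ser_rows = [
        [lbl, s["n_cases"], s["n_serious"], s["pct_serious"], s["n_death"],
         s["pct_death"]]
        for lbl, s in summary.seriousness.items()
    ]
    _write_tsv(
        outdir / "seriousness.tsv",
        ["band", "n_cases", "n_serious", "pct_serious", "n_death", "pct_death"],
        ser_rows, stamp,
    )

    out_rows: list[list] = []
    for lbl, osum in summary.outcomes.items():
        out_rows.append(
            [lbl, "known_outcome", osum.known_n, osum.pct_known_of_cases]
        )
        out_rows.append(
            [lbl, "recovered_or_recovering", *osum.recovered_or_recovering]
        )
        for outcome, n, pct in osum.distribution:
            out_rows.append([lbl, outcome, n, pct])
    _write_tsv(outdir / "outcomes.tsv", ["band", "row", "n", "pct"], out_rows, stamp)

    for lbl, drugs in summary.top_drugs.items():
        _write_tsv(
            outdir / f"top_drugs__{lbl}.tsv",
            ["drug", "n", "pct_of_cases"],
            [list(row) for row in drugs[:25]],
            stamp,
        )


def _scan_block(
    rs: ReportSet,
    queries: dict[str, PtQuery],
    names: Sequence[str],
    cfg: PipelineConfig,
    outdir: Path,
    stamp: str,
) -> dict[tuple[str, str], SignalTable]:
    tables: dict[tuple[str, str], SignalTable] = {}
    band_labels = list(cfg.bands) + [ALL_PEDIATRIC.label]
    for name in names:
        for lbl in band_labels:
            table = run_signal_scan(
                rs,
                queries[name],
                lbl,
                roles=cfg.roles,
                min_cases=cfg.min_cases,
                background=cfg.background,
            )
            tables[(name, lbl)] = table
            fname = f"{name.replace(' ', '_')}__{lbl}.tsv"
            write_signal_table_tsv(table, outdir / fname, stamp)
            logger.info(
                "scan query=%s band=%s drugs=%d signals=%d",
                name, lbl, len(table.rows),
                sum(s.is_signal for s in table.rows),
            )
    return tables


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run simulate/load -> query -> scan -> report; returns the output dir.

    The healthcare-professional sensitivity scan is the primary scan applied
    to the reporter-filtered report set — the same code path end to end.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pvsignal")
    root.addHandler(handler)
    root.setLevel(cfg.log_level)
    stamp = f"pvsignal config={cfg.config_hash()} seed={cfg.seed}"
    try:
        return _run_pipeline_inner(cfg, outdir, stamp)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(cfg: PipelineConfig, outdir: Path, stamp: str) -> Path:
    # stage: acquire reports
    try:
        if cfg.reports:
            rs = read_report_set(cfg.reports)
            logger.info("load reports=%d path=%s", len(rs), cfg.reports)
        else:
            from .synthetic import default_pediatric_config, generate_report_set

            gen_cfg = default_pediatric_config(scale=cfg.simulate_scale, seed=cfg.seed)
            if cfg.simulate_n is not None:
                gen_cfg = gen_cfg.model_copy(update={"n_reports": cfg.simulate_n})
            rs, _truth = generate_report_set(gen_cfg)
            write_report_set(rs, outdir / "reports.jsonl")
            logger.info("simulate reports=%d scale=%d seed=%d",
                        len(rs), cfg.simulate_scale, cfg.seed)
    except Exception as exc:
        raise PipelineError(f"stage 'acquire-reports' failed: {exc}") from exc

    queries = _load_queries(cfg)

    # stage: exclusions audit
    n_out = sum(classify_age_band(r) == "out_of_scope" for r in rs)
    logger.info(
        "age-banding pediatric=%d out_of_scope_excluded=%d total=%d",
        len(rs) - n_out, n_out, len(rs),
    )

    # stage: descriptive cohort
    try:
        summary = cohort_characteristics(rs, queries[cfg.primary])
        _write_cohort_tables(summary, outdir, stamp)
        logger.info(
            "cohort query=%s cases=%s", cfg.primary,
            {k: v for k, v in summary.totals.items()},
        )
    except Exception as exc:
        raise PipelineError(f"stage 'cohort-characteristics' failed: {exc}") from exc

    # stage: co-reported PTs and feature distributions
    try:
        feature_queries = [queries[name] for name in cfg.features]
        for lbl in list(cfg.bands) + [ALL_PEDIATRIC.label]:
            cs = select_cases(rs, queries[cfg.primary], lbl)
            if len(cs) > 0:
                ranked = co_reported_pt_counts(cs)[:20]
                _write_tsv(
                    outdir / f"co_reported__{lbl}.tsv",
                    ["pt", "n", "pct_of_cases"],
                    [list(row) for row in ranked],
                    stamp,
                )
            feats = feature_distribution(rs, feature_queries, lbl)
            _write_tsv(
                outdir / f"features__{lbl}.tsv",
                ["feature", "n_cases"],
                [list(row) for row in feats],
                stamp,
            )
    except Exception as exc:
        raise PipelineError(f"stage 'features' failed: {exc}") from exc

    # stage: co-occurrence of the primary PT with feature terms
    try:
        co_rows = []
        for lbl in list(cfg.bands) + [ALL_PEDIATRIC.label]:
            for name in cfg.co_occurrence:
                cs = co_occurrence_cases(
                    rs, queries[cfg.primary], queries[name], lbl
                )
                co_rows.append([lbl, name, len(cs)])
        _write_tsv(
            outdir / "cooccurrence.tsv", ["band", "with_pt", "n_cases"],
            co_rows, stamp,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'co-occurrence' failed: {exc}") from exc

    # stage: disproportionality scans
    try:
        scan_names = [cfg.primary] + list(cfg.features)
        _scan_block(rs, queries, scan_names, cfg, outdir / "signals", stamp)
    except Exception as exc:
        raise PipelineError(f"stage 'signal-scan' failed: {exc}") from exc

    # stage: HCP sensitivity — identical scan on the reporter-filtered set
    try:
        rs_hcp = filter_report_set_by_reporter(rs, cfg.hcp_qualifications)
        logger.info("hcp-filter reports=%d of %d", len(rs_hcp), len(rs))
        _scan_block(
            rs_hcp, queries, [cfg.primary] + list(cfg.features), cfg,
            outdir / "signals_hcp", stamp,
        )
        hcp_rows = []
        for name in cfg.sensitivity:
            cs = select_cases(rs, queries[name], ALL_PEDIATRIC)
            n_hcp = len(
                [r for r in cs if r.reporter_qualification in cfg.hcp_qualifications]
            )
            pct = percentage(n_hcp, len(cs)) if len(cs) else 0.0
            hcp_rows.append([name, len(cs), n_hcp, pct])
        _write_tsv(
            outdir / "hcp_proportions.tsv",
            ["pt", "n_cases", "n_hcp", "pct_hcp"],
            hcp_rows, stamp,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'hcp-sensitivity' failed: {exc}") from exc

    # stage: manifest
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "config_hash": cfg.config_hash(),
        "n_reports": len(rs),
        "n_out_of_scope_age": n_out,
        "pediatric_case_totals": summary.totals,
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete outdir=%s", outdir)
    return outdir
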