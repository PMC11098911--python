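"""Readers and writers for the JSON-Lines report format and PT-query files.

One report per line, UTF-8, newline-terminated, with keys in a fixed order
(``REPORT_KEY_ORDER``) and set-valued fields written sorted, so that
``write -> read -> write`` is byte-identical.

PT-query files are YAML mappings ``query name -> list of preferred terms``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import yaml
from pydantic import ValidationError

from .icsr import IcsrReport, PtQuery, ReportSet, validate_report

#: Documented, fixed serialization order of report keys.
REPORT_KEY_ORDER = (
    "report_id",
    "age_value",
    "age_unit",
    "sex",
    "country",
    "reporter_qualification",
    "drugs",
    "reactions",
    "serious",
    "seriousness_criteria",
    "outcome",
)


class ReportReadError(ValueError):
    """Raised when a report file is malformed; the message names the line."""


def _report_to_dict(r: IcsrReport) -> dict:
    return {
        "report_id": r.report_id,
        "age_value": r.age_value,
        "age_unit": r.age_unit,
        "sex": r.sex,
        "country": r.country,
        "reporter_qualification": r.reporter_qualification,
        "drugs": [{"drug_name": d.drug_name, "role": d.role} for d in r.drugs],
        "reactions": sorted(r.reactions),
        "serious": r.serious,
        "seriousness_criteria": sorted(r.seriousness_criteria),
        "outcome": r.outcome,
    }


def report_to_json_line(r: IcsrReport) -> str:
    return json.dumps(_report_to_dict(r), ensure_ascii=False, separators=(",", ":"))


def write_report_set(rs: ReportSet, path: Union[str, Path]) -> Path:
    """Write a report set as JSON Lines; returns the path written."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for r in rs.reports:
            fh.write(report_to_json_line(r))
            fh.write("\n")
    return path


def read_report_set(path: Union[str, Path], format: str = "jsonl") -> ReportSet:
    """Read a JSON-Lines report file, validating every record.

    Raises :class:`ReportReadError` naming the 1-based line number on a
    malformed line, a schema violation, an invariant violation, or a
    duplicate ``report_id``.
    """
    if format != "jsonl":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    reports: list[IcsrReport] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ReportReadError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            try:
                report = IcsrReport.model_validate(obj)
            except ValidationError as exc:
                first = exc.errors()[0]
                loc = ".".join(str(p) for p in first["loc"]) or "<record>"
                raise ReportReadError(
                    f"line {lineno}: invalid report field '{loc}': {first['msg']}"
                ) from exc
            violations = validate_report(report)
            if violations:
                raise ReportReadError(f"line {lineno}: {violations[0]}")
            if report.report_id in seen:
                raise ReportReadError(
                    f"line {lineno}: duplicate report_id '{report.report_id}'"
                )
            seen.add(report.report_id)
            reports.append(report)
    return ReportSet(reports=reports, provenance=str(path))


def read_pt_queries(path: Union[str, Path]) -> dict[str, PtQuery]:
    """Read a YAML PT-query file mapping query name -> list of PTs."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: PT-query file must be a non-empty mapping")
    queries: dict[str, PtQuery] = {}
    for name, pts in raw.items():
        if isinstance(pts, str):
            pts = [pts]
        queries[str(name)] = PtQuery(name=str(name), pts=frozenset(pts))
    return queries


def write_pt_queries(queries: dict[str, PtQuery], path: Union[str, Path]) -> Path:
    path = Path(path)
    payload = {name: sorted(q.pts) for name, q in queries.items()}
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True, allow_unicode=True)
    return path
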