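"""Readers and writers: study files (JSON/CSV) and score tables (CSV/xlsx).

The study JSON document mirrors the domain model one-to-one::

    {"panels": [{"id", "hazard", "region",
                 "items": [{"id", "kind", "scale", "units", "bounds", "realization"}],
                 "experts": [ids],
                 "assessments": [{"expert", "item", "q05", "q50", "q95"}]}],
     "experts": {id: label}}

An equivalent long-form CSV (one assessment per row, panel and item
metadata repeated) is accepted and produced.  Floats are serialized with
``repr``, which guarantees an exact numeric round-trip.

Score tables are tidy CSV with columns panel, assessor, kind,
statistical_accuracy, informativeness, combined; spreadsheet (.xlsx) input
in the same shape is accepted, optionally through a column/sheet mapping
for externally produced files whose headers differ.  Assessor labels
``pwg``/``pwi``/``ew`` (case-insensitive) denote the pooled DM rows; other
labels are experts.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .analysis import DM_KINDS, SCORE_TABLE_COLUMNS, validate_score_table
from .study import Item, Panel, QuantileTriple, Study, validate_study

__all__ = [
    "StudyFormatError",
    "read_study",
    "write_study",
    "read_score_table",
    "write_score_table",
]

_CSV_COLUMNS = [
    "panel", "hazard", "region", "item", "kind", "scale", "units",
    "bound_lo", "bound_hi", "realization", "expert", "q05", "q50", "q95",
]


class StudyFormatError(ValueError):
    """A file does not parse or validate as a Study / score table."""


def _fmt(x: Optional[float]) -> Optional[str]:
    return None if x is None else repr(float(x))


def _study_to_doc(study: Study, anonymize: bool = False) -> dict:
    labels = study.expert_labels
    if anonymize:
        labels = {e: f"Expert {i + 1}" for i, e in enumerate(study.expert_ids)}
    return {
        "panels": [
            {
                "id": p.id,
                "hazard": p.hazard,
                "region": p.region,
                "items": [
                    {
                        "id": it.id,
                        "kind": it.kind,
                        "scale": it.scale,
                        "units": it.units,
                        "bounds": list(it.bounds) if it.bounds is not None else None,
                        "realization": it.realization,
                    }
                    for it in p.items
                ],
                "experts": list(p.experts),
                "assessments": [
                    {"expert": e, "item": it.id,
                     "q05": p.assessments[(e, it.id)].q05,
                     "q50": p.assessments[(e, it.id)].q50,
                     "q95": p.assessments[(e, it.id)].q95}
                    for e in p.experts
                    for it in p.items
                    if (e, it.id) in p.assessments
                ],
            }
            for p in study.panels
        ],
        "experts": dict(labels),
    }


def _doc_to_study(doc: dict, source: str) -> Study:
    try:
        panels = []
        for pi, pd_doc in enumerate(doc["panels"]):
            loc = f"{source}#/panels/{pi}"
            items = []
            for ii, item_doc in enumerate(pd_doc.get("items", [])):
                bounds = item_doc.get("bounds")
                items.append(
                    Item(
                        id=str(item_doc["id"]),
                        kind=item_doc.get("kind", "calibration"),
                        scale=item_doc.get("scale", "uniform"),
                        units=item_doc.get("units", ""),
                        realization=item_doc.get("realization"),
                        bounds=tuple(bounds) if bounds is not None else None,
                    )
                )
            assessments = {}
            for ai, a in enumerate(pd_doc.get("assessments", [])):
                try:
                    triple = QuantileTriple(
                        q05=float(a["q05"]), q50=float(a["q50"]), q95=float(a["q95"])
                    )
                except (TypeError, ValueError) as exc:
                    raise StudyFormatError(
                        f"{loc}/assessments/{ai}: malformed quantiles: {exc}"
                    ) from exc
                assessments[(str(a["expert"]), str(a["item"]))] = triple
            panels.append(
                Panel(
                    id=str(pd_doc["id"]),
                    hazard=pd_doc.get("hazard", ""),
                    region=pd_doc.get("region", ""),
                    experts=[str(e) for e in pd_doc.get("experts", [])],
                    items=items,
                    assessments=assessments,
                )
            )
        study = Study(
            panels=panels,
            expert_labels={str(k): str(v) for k, v in doc.get("experts", {}).items()},
        )
    except KeyError as exc:
        raise StudyFormatError(f"{source}: missing required field {exc}") from exc
    violations = validate_study(study)
    if violations:
        raise StudyFormatError(
            f"{source}: study failed validation:\n  " + "\n  ".join(violations)
        )
    return study


def write_study(study: Study, path: Union[str, Path], anonymize: bool = False) -> None:
    """Write a study as JSON (``.json``) or long-form CSV (``.csv``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_study_csv(study, path, anonymize)
        return
    doc = _study_to_doc(study, anonymize)
    path.write_text(json.dumps(doc, indent=1))


def read_study(path: Union[str, Path]) -> Study:
    """Read a study from JSON or long-form CSV; validates before returning."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_study_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise StudyFormatError(f"{path}: not valid JSON: {exc}") from exc
    return _doc_to_study(doc, str(path))


def _write_study_csv(study: Study, path: Path, anonymize: bool = False) -> None:
    rows = []
    for p in study.panels:
        for e in p.experts:
            for it in p.items:
                t = p.assessments[(e, it.id)]
                rows.append(
                    {
                        "panel": p.id, "hazard": p.hazard, "region": p.region,
                        "item": it.id, "kind": it.kind, "scale": it.scale,
                        "units": it.units,
                        "bound_lo": _fmt(None if it.bounds is None else it.bounds[0]),
                        "bound_hi": _fmt(None if it.bounds is None else it.bounds[1]),
                        "realization": _fmt(it.realization),
                        "expert": e,
                        "q05": _fmt(t.q05), "q50": _fmt(t.q50), "q95": _fmt(t.q95),
                    }
                )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _opt_float(v, where: str) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    try:
        return float(v)
    except (TypeError, ValueError) as exc:
        raise StudyFormatError(f"{where}: malformed number {v!r}") from exc


def _read_study_csv(path: Path) -> Study:
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # parser errors vary by pandas version
        raise StudyFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise StudyFormatError(f"{path}: missing columns {missing}")
    panels: dict[str, dict] = {}
    for idx, row in frame.iterrows():
        where = f"{path}:row {idx + 2}"  # header is line 1
        pid = row["panel"]
        p = panels.setdefault(
            pid,
            {"hazard": row["hazard"] if isinstance(row["hazard"], str) else "",
             "region": row["region"] if isinstance(row["region"], str) else "",
             "items": {}, "experts": [], "assessments": {}},
        )
        iid = row["item"]
        if iid not in p["items"]:
            lo = _opt_float(row["bound_lo"], where)
            hi = _opt_float(row["bound_hi"], where)
            p["items"][iid] = Item(
                id=iid,
                kind=row["kind"],
                scale=row["scale"],
                units=row["units"] if isinstance(row["units"], str) else "",
                realization=_opt_float(row["realization"], where),
                bounds=None if lo is None or hi is None else (lo, hi),
            )
        if row["expert"] not in p["experts"]:
            p["experts"].append(row["expert"])
        q05 = _opt_float(row["q05"], where)
        q50 = _opt_float(row["q50"], where)
        q95 = _opt_float(row["q95"], where)
        if None in (q05, q50, q95):
            raise StudyFormatError(f"{where}: missing quantile value")
        p["assessments"][(row["expert"], iid)] = QuantileTriple(q05, q50, q95)
    study = Study(
        panels=[
            Panel(id=pid, hazard=p["hazard"], region=p["region"],
                  experts=p["experts"], items=list(p["items"].values()),
                  assessments=p["assessments"])
            for pid, p in panels.items()
        ],
        expert_labels={},
    )
    study.expert_labels = {e: e for e in study.expert_ids}
    violations = validate_study(study)
    if violations:
        raise StudyFormatError(
            f"{path}: study failed validation:\n  " + "\n  ".join(violations)
        )
    return study


def _normalize_score_frame(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    frame = frame.rename(columns={c: str(c).strip().lower() for c in frame.columns})
    aliases = {
        "panel_id": "panel", "expert": "assessor", "name": "assessor",
        "accuracy": "statistical_accuracy", "calibration": "statistical_accuracy",
        "information": "informativeness", "info": "informativeness",
        "combined_score": "combined",
    }
    frame = frame.rename(columns={k: v for k, v in aliases.items() if k in frame.columns})
    required = ["panel", "assessor", "statistical_accuracy", "informativeness"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise StudyFormatError(f"{source}: missing columns {missing}")
    out = frame.copy()
    out["assessor"] = out["assessor"].astype(str)
    if "kind" not in out.columns:
        out["kind"] = [
            a.lower() if a.lower() in DM_KINDS else "expert" for a in out["assessor"]
        ]
    else:
        out["kind"] = out["kind"].astype(str).str.strip().str.lower()
        bad = ~out["kind"].isin(("expert",) + DM_KINDS)
        if bad.any():
            idx = int(out.index[bad][0])
            raise StudyFormatError(
                f"{source}:row {idx + 2}: unknown assessor kind "
                f"{out.loc[out.index[bad][0], 'kind']!r}"
            )
    out.loc[out["kind"].isin(DM_KINDS), "assessor"] = out.loc[
        out["kind"].isin(DM_KINDS), "assessor"
    ].str.lower()
    for col in ("statistical_accuracy", "informativeness", "combined"):
        if col not in out.columns:
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            idx = int(out.index[bad][0])
            raise StudyFormatError(
                f"{source}:row {idx + 2}: malformed numeric in column {col!r}: "
                f"{out.loc[out.index[bad][0], col]!r}"
            )
        out[col] = coerced
    if "combined" not in out.columns or out["combined"].isna().all():
        out["combined"] = out["statistical_accuracy"] * out["informativeness"]
    return out[list(SCORE_TABLE_COLUMNS)].reset_index(drop=True)


def read_score_table(
    path: Union[str, Path],
    mapping: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Read a score table from CSV or xlsx.

    ``mapping`` adapts externally produced files: ``{"sheet": name,
    "columns": {canonical: source_header}}``.  DM rows are recognized by
    assessor labels pwg/pwi/ew (or an explicit ``kind`` column).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheet = (mapping or {}).get("sheet", 0)
        frame = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        frame = pd.read_csv(path)
    columns = (mapping or {}).get("columns")
    if columns:
        frame = frame.rename(columns={v: k for k, v in columns.items()})
    table = _normalize_score_frame(frame, str(path))
    problems = validate_score_table(table)
    if problems:
        raise StudyFormatError(
            f"{path}: score table failed validation:\n  " + "\n  ".join(problems)
        )
    return table


def write_score_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a score table as CSV with full-precision floats."""
    out = table[list(SCORE_TABLE_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format=None)
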