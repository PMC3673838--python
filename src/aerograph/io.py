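"""Readers and writers for study tables and graph exchange formats.

The canonical input is a *study table*: one row per study with columns

    id, label, phase, year, seq, outcome, status, children, same_report_children

``children`` and ``same_report_children`` hold semicolon-separated id
lists; an empty cell or a dash ("–" or "-") means no children.  ``seq``
defaults to 0 and ``status`` to ``completed``.  Outcome and status labels
are parsed case-insensitively and stored lowercase.  Unknown columns are
preserved on a round-trip.  Tables come as UTF-8 CSV (comma), TSV (tab)
or JSON (nested ``{phase_schema, studies, edges}``).

Graphs additionally export to Graphviz DOT and to GraphML, with node
attributes ``phase, year, seq, outcome, status`` and the edge attribute
``same_report``.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import IO, Iterable

import networkx as nx

from .core import (
    AeroGraph,
    AeroGraphError,
    LineageEdge,
    Outcome,
    PhaseSchema,
    Status,
    Study,
)

__all__ = [
    "read_study_table",
    "write_study_table",
    "export_graph",
    "TableFormatError",
]

REQUIRED_COLUMNS = ("id", "phase", "year")
STANDARD_COLUMNS = (
    "id",
    "label",
    "phase",
    "year",
    "seq",
    "outcome",
    "status",
    "children",
    "same_report_children",
)
_EMPTY_CELLS = {"", "-", "–", "—"}


class TableFormatError(AeroGraphError):
    """A study table is malformed (missing columns, dangling ids, …)."""


def _is_empty(cell: str | None) -> bool:
    return cell is None or cell.strip() in _EMPTY_CELLS


def _split_ids(cell: str | None) -> list[str]:
    if _is_empty(cell):
        return []
    return [tok.strip() for tok in cell.split(";") if tok.strip()]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".tab"):
        return "tsv"
    if suffix in (".json",):
        return "json"
    raise TableFormatError(
        f"cannot infer table format from {path.name!r}; pass format="
    )


def _row_to_study(row: dict[str, str], rownum: int) -> tuple[Study, list[LineageEdge]]:
    def fail(msg: str) -> TableFormatError:
        return TableFormatError(f"row {rownum}: {msg}")

    sid = (row.get("id") or "").strip()
    if not sid:
        raise fail("missing study id")
    try:
        year = int(str(row["year"]).strip())
    except (KeyError, ValueError):
        raise fail(f"study {sid!r}: year {row.get('year')!r} is not an integer")
    seq_cell = row.get("seq")
    try:
        seq = 0 if _is_empty(seq_cell) else int(str(seq_cell).strip())
    except ValueError:
        raise fail(f"study {sid!r}: seq {seq_cell!r} is not an integer")
    status_cell = row.get("status")
    status = (
        Status.COMPLETED if _is_empty(status_cell) else Status.parse(status_cell)
    )
    outcome_cell = row.get("outcome")
    outcome = None if _is_empty(outcome_cell) else Outcome.parse(outcome_cell)
    if status is Status.COMPLETED and outcome is None:
        raise fail(f"completed study {sid!r} has no outcome")
    extra = {
        k: v
        for k, v in row.items()
        if k not in STANDARD_COLUMNS and k is not None and not _is_empty(v)
    }
    try:
        study = Study(
            id=sid,
            phase=(row.get("phase") or "").strip(),
            year=year,
            label=("" if _is_empty(row.get("label")) else row["label"].strip()),
            seq=seq,
            outcome=outcome,
            status=status,
            extra=extra,
        )
    except AeroGraphError as exc:
        raise fail(str(exc)) from None
    edges = [LineageEdge(sid, c) for c in _split_ids(row.get("children"))]
    edges += [
        LineageEdge(sid, c, same_report=True)
        for c in _split_ids(row.get("same_report_children"))
    ]
    return study, edges


def _read_delimited(
    handle: IO[str], delimiter: str, schema: PhaseSchema
) -> AeroGraph:
    reader = csv.DictReader(handle, delimiter=delimiter)
    if reader.fieldnames is None:
        raise TableFormatError("empty table: a header row is required")
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise TableFormatError(f"missing required column(s) {missing}")
    studies: list[Study] = []
    edges: list[LineageEdge] = []
    for rownum, row in enumerate(reader, start=2):  # row 1 is the header
        study, study_edges = _row_to_study(row, rownum)
        studies.append(study)
        edges.extend(study_edges)
    return _assemble(schema, studies, edges)


def _assemble(
    schema: PhaseSchema, studies: list[Study], edges: list[LineageEdge]
) -> AeroGraph:
    known = {s.id for s in studies}
    dangling = sorted({e.child for e in edges} - known)
    if dangling:
        raise TableFormatError(
            f"children reference unknown study id(s) {dangling}"
        )
    return AeroGraph(schema, studies, edges)


def _read_json(handle: IO[str]) -> AeroGraph:
    doc = json.load(handle)
    if not isinstance(doc, dict) or "studies" not in doc:
        raise TableFormatError("JSON table must be an object with 'studies'")
    schema_doc = doc.get("phase_schema")
    if schema_doc is None:
        schema = PhaseSchema.default()
    else:
        schema = PhaseSchema(
            names=tuple(p["name"] for p in schema_doc),
            labels={
                p["name"]: p["label"] for p in schema_doc if p.get("label")
            },
        )
    studies = []
    for i, rec in enumerate(doc["studies"]):
        outcome = rec.get("outcome")
        studies.append(
            Study(
                id=rec["id"],
                phase=rec["phase"],
                year=int(rec["year"]),
                label=rec.get("label", ""),
                seq=int(rec.get("seq", 0)),
                outcome=None if not outcome else Outcome.parse(outcome),
                status=Status.parse(rec.get("status", "completed")),
                extra=dict(rec.get("extra", {})),
            )
        )
    edges = [
        LineageEdge(e["parent"], e["child"], bool(e.get("same_report", False)))
        for e in doc.get("edges", [])
    ]
    return _assemble(schema, studies, edges)


def read_study_table(
    source: str | Path | IO[str],
    format: str | None = None,
    phase_schema: PhaseSchema | None = None,
) -> AeroGraph:
    """Load and validate a study table from a path or open text stream.

    ``format`` is one of ``csv``, ``tsv``, ``json``; inferred from the
    file suffix when omitted.  Problems are reported with row numbers.
    JSON tables carry their own phase schema; delimited tables use
    ``phase_schema`` (default ladder when omitted).
    """
    schema = phase_schema or PhaseSchema.default()
    if hasattr(source, "read"):
        if format is None:
            raise TableFormatError("format= is required when reading a stream")
        handle: IO[str] = source  # type: ignore[assignment]
        close = False
    else:
        path = Path(source)
        format = format or _infer_format(path)
        handle = open(path, encoding="utf-8", newline="")
        close = True
    try:
        if format == "csv":
            return _read_delimited(handle, ",", schema)
        if format == "tsv":
            return _read_delimited(handle, "\t", schema)
        if format == "json":
            return _read_json(handle)
        raise TableFormatError(f"unknown table format {format!r}")
    finally:
        if close:
            handle.close()


def _table_rows(graph: AeroGraph) -> tuple[list[str], list[dict[str, str]]]:
    children: dict[str, list[str]] = {sid: [] for sid in graph.studies}
    same_report: dict[str, list[str]] = {sid: [] for sid in graph.studies}
    for e in graph.edges:
        (same_report if e.same_report else children)[e.parent].append(e.child)
    extra_cols = sorted({k for s in graph.studies.values() for k in s.extra})
    columns = list(STANDARD_COLUMNS) + extra_cols
    rows = []
    for sid in graph.temporal_order():
        s = graph.study(sid)
        row = {
            "id": s.id,
            "label": s.label,
            "phase": s.phase,
            "year": str(s.year),
            "seq": str(s.seq),
            "outcome": s.outcome.value if s.outcome else "",
            "status": s.status.value,
            "children": ";".join(sorted(children[sid])),
            "same_report_children": ";".join(sorted(same_report[sid])),
        }
        row.update({k: s.extra.get(k, "") for k in extra_cols})
        rows.append(row)
    return columns, rows


def _graph_to_json_doc(graph: AeroGraph) -> dict:
    doc: dict = {
        "phase_schema": [
            # explicit labels only, so a round-trip reproduces the schema
            {"name": name, "label": graph.phase_schema.labels[name]}
            if name in graph.phase_schema.labels
            else {"name": name}
            for name in graph.phase_schema.names
        ],
        "studies": [],
        "edges": [],
    }
    for sid in graph.temporal_order():
        s = graph.study(sid)
        rec: dict = {
            "id": s.id,
            "label": s.label,
            "phase": s.phase,
            "year": s.year,
            "seq": s.seq,
            "outcome": s.outcome.value if s.outcome else None,
            "status": s.status.value,
        }
        if s.extra:
            rec["extra"] = dict(s.extra)
        doc["studies"].append(rec)
    for e in sorted(graph.edges, key=lambda e: e.key):
        doc["edges"].append(
            {"parent": e.parent, "child": e.child, "same_report": e.same_report}
        )
    return doc


def write_study_table(
    graph: AeroGraph,
    target: str | Path | IO[str] | None = None,
    format: str = "csv",
) -> str:
    """Serialize a graph as a study table; round-trips with the reader.

    Returns the document as a string and, when ``target`` is given,
    also writes it to that path or stream.
    """
    if format in ("csv", "tsv"):
        buf = _io.StringIO()
        columns, rows = _table_rows(graph)
        writer = csv.DictWriter(
            buf, fieldnames=columns, delimiter="," if format == "csv" else "\t",
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(rows)
        text = buf.getvalue()
    elif format == "json":
        text = json.dumps(_graph_to_json_doc(graph), indent=2, ensure_ascii=False)
        text += "\n"
    else:
        raise TableFormatError(f"unknown table format {format!r}")
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)  # type: ignore[union-attr]
        else:
            Path(target).write_text(text, encoding="utf-8")
    return text


def _dot_quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _export_dot(graph: AeroGraph) -> str:
    lines = ["digraph aero {"]
    for sid in graph.temporal_order():
        s = graph.study(sid)
        attrs = [
            f"phase={_dot_quote(s.phase)}",
            f"year={_dot_quote(str(s.year))}",
            f"outcome={_dot_quote(s.outcome.value if s.outcome else '')}",
            f"status={_dot_quote(s.status.value)}",
        ]
        lines.append(f"  {_dot_quote(sid)} [{', '.join(attrs)}];")
    for e in sorted(graph.edges, key=lambda e: e.key):
        attrs = f" [dir=none, same_report=\"true\"]" if e.same_report else ""
        lines.append(
            f"  {_dot_quote(e.parent)} -> {_dot_quote(e.child)}{attrs};"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _export_graphml(graph: AeroGraph) -> str:
    g = graph.to_networkx()
    buf = _io.BytesIO()
    nx.write_graphml(g, buf, named_key_ids=True)
    return buf.getvalue().decode("utf-8")


def export_graph(graph: AeroGraph, format: str = "dot") -> str:
    """Export to an exchange format: ``dot``, ``graphml`` or ``json``.

    Node attributes carry phase, year, outcome and status; edges carry
    the same-report flag (DOT additionally sets ``dir=none`` on them so
    standard Graphviz renders no arrowhead).
    """
    fmt = format.lower()
    if fmt == "dot":
        return _export_dot(graph)
    if fmt == "graphml":
        return _export_graphml(graph)
    if fmt == "json":
        return json.dumps(_graph_to_json_doc(graph), indent=2, ensure_ascii=False) + "\n"
    raise TableFormatError(f"unknown export format {format!r}")
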