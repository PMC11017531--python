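"""Readers and writers for every prevcal file format.

Formats
-------
* Confusion-matrix JSON (``tp``/``fn``/``fp``/``tn`` + optional metadata)
  and 2x2 CSV with mandatory ``actual_*`` / ``pred_*`` headers.  The CSV
  orientation (rows = actual or rows = predicted) is resolved from the
  headers, never positionally — silent transposition is the classic
  confusion-matrix bug.  Fractional cells are accepted only when the
  document carries a ``calibrated`` flag; raw validation matrices must be
  integers.
* Label files: CSV/TSV with mandatory ``actual``/``predicted`` header,
  parsed row by row (streaming).
* Sweep-curve CSV (``prevalence,value`` plus ``# metric/sen/spe`` metadata
  lines) and an equivalent JSON document.
* Scenario JSON and comparison-report JSON.

All CSV output is comma-separated UTF-8 with a locale-independent decimal
point; floats are serialised with ``repr`` so every writer/reader pair
round-trips bit-compatibly.  JSON documents are validated against the
schemas shipped under ``prevcal/schemas`` by a small built-in checker.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

from .calibration import SweepCurve
from .core import UNDEFINED, ConfusionMatrix, PerformanceProfile, is_undefined
from .exceptions import FormatError, PrevcalError
from .report import ComparisonReport
from .scenarios import Scenario

__all__ = [
    "read_confusion_matrix",
    "write_confusion_matrix",
    "read_labels",
    "write_labels",
    "read_curve",
    "write_curve",
    "read_report",
    "write_report",
    "read_scenario",
    "write_scenario",
    "load_schema",
    "validate_document",
]

_CELL_KEYS = ("tp", "fn", "fp", "tn")
_ACTUAL_HEADERS = {"actual_positive": 1, "actual_negative": 0}
_PRED_HEADERS = {"pred_positive": 1, "pred_negative": 0}


# ---------------------------------------------------------------------------
# schema support (minimal JSON-Schema subset checker)

def load_schema(name: str) -> dict:
    """Load one of the shipped schemas: matrix, scenario, curve or report."""
    try:
        text = (
            resources.files("prevcal")
            .joinpath("schemas", f"{name}.schema.json")
            .read_text(encoding="utf-8")
        )
    except FileNotFoundError as exc:
        raise PrevcalError(f"no shipped schema named {name!r}") from exc
    return json.loads(text)


def validate_document(doc: object, schema: dict, path: str = "$") -> None:
    """Validate *doc* against a JSON-Schema subset; raise FormatError on failure.

    Supported keywords: type, properties, required, items, enum,
    minimum/maximum.  Intentionally small — the shipped schemas only use
    these.
    """
    expected = schema.get("type")
    if expected is not None:
        kinds = expected if isinstance(expected, list) else [expected]
        if not any(_is_type(doc, kind) for kind in kinds):
            raise FormatError(f"{path}: expected type {expected}, got {type(doc).__name__}")
    if "enum" in schema and doc not in schema["enum"]:
        raise FormatError(f"{path}: value {doc!r} not one of {schema['enum']}")
    if isinstance(doc, (int, float)) and not isinstance(doc, bool):
        if "minimum" in schema and doc < schema["minimum"]:
            raise FormatError(f"{path}: value {doc!r} below minimum {schema['minimum']}")
        if "maximum" in schema and doc > schema["maximum"]:
            raise FormatError(f"{path}: value {doc!r} above maximum {schema['maximum']}")
    if isinstance(doc, dict):
        for key in schema.get("required", ()):
            if key not in doc:
                raise FormatError(f"{path}: missing required field {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in doc:
                validate_document(doc[key], sub, f"{path}.{key}")
    if isinstance(doc, list) and "items" in schema:
        for i, item in enumerate(doc):
            validate_document(item, schema["items"], f"{path}[{i}]")


def _is_type(value: object, kind: str) -> bool:
    if kind == "object":
        return isinstance(value, dict)
    if kind == "array":
        return isinstance(value, list)
    if kind == "string":
        return isinstance(value, str)
    if kind == "boolean":
        return isinstance(value, bool)
    if kind == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if kind == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if kind == "null":
        return value is None
    raise PrevcalError(f"unsupported schema type {kind!r}")


# ---------------------------------------------------------------------------
# confusion matrices

def read_confusion_matrix(path: str | Path, format: str = "auto") -> ConfusionMatrix:
    """Read a confusion matrix from JSON or CSV (``format='auto'`` by suffix)."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "json":
        return _read_matrix_json(path)
    return _read_matrix_csv(path)


def _resolve_format(path: Path, format: str) -> str:
    if format not in ("auto", "json", "csv"):
        raise PrevcalError(f"format must be auto, json or csv, got {format!r}")
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise FormatError(f"cannot infer format from suffix of {path}; pass format=")


def _read_matrix_json(path: Path) -> ConfusionMatrix:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    validate_document(doc, load_schema("matrix"), str(path))
    calibrated = bool(doc.get("calibrated", False))
    cells = {key: float(doc[key]) for key in _CELL_KEYS}
    try:
        return ConfusionMatrix(**cells, strict_integer=not calibrated)
    except PrevcalError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_matrix_csv(path: Path) -> ConfusionMatrix:
    calibrated = False
    rows: list[list[str]] = []
    with path.open(newline="", encoding="utf-8") as handle:
        for raw in csv.reader(handle):
            if not raw or all(not cell.strip() for cell in raw):
                continue
            if raw[0].lstrip().startswith("#"):
                comment = raw[0].lstrip("# ").strip().lower()
                if comment.replace(" ", "") == "calibrated:true":
                    calibrated = True
                continue
            rows.append([cell.strip() for cell in raw])
    if len(rows) != 3 or any(len(row) != 3 for row in rows):
        raise FormatError(
            f"{path}: expected a 2x2 table with one header row and one header "
            f"column, got {len(rows)} data rows"
        )
    col_labels = [_normalise_header(cell) for cell in rows[0][1:]]
    row_labels = [_normalise_header(rows[1][0]), _normalise_header(rows[2][0])]
    cells: dict[tuple[int, int], float] = {}  # (actual, predicted) -> count
    for r, row_label in enumerate(row_labels):
        for c, col_label in enumerate(col_labels):
            value = _parse_count(rows[r + 1][c + 1], path)
            if row_label in _ACTUAL_HEADERS and col_label in _PRED_HEADERS:
                key = (_ACTUAL_HEADERS[row_label], _PRED_HEADERS[col_label])
            elif row_label in _PRED_HEADERS and col_label in _ACTUAL_HEADERS:
                key = (_ACTUAL_HEADERS[col_label], _PRED_HEADERS[row_label])
            else:
                raise FormatError(
                    f"{path}: ambiguous headers {rows[1][0]!r}/{rows[0][1]!r}; row and "
                    "column headers must pair actual_positive/actual_negative with "
                    "pred_positive/pred_negative (either orientation)"
                )
            if key in cells:
                raise FormatError(f"{path}: duplicate cell for {key}")
            cells[key] = value
    if len(cells) != 4:
        raise FormatError(f"{path}: missing confusion-matrix cells")
    try:
        return ConfusionMatrix(
            tp=cells[(1, 1)],
            fn=cells[(1, 0)],
            fp=cells[(0, 1)],
            tn=cells[(0, 0)],
            strict_integer=not calibrated,
        )
    except PrevcalError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _normalise_header(cell: str) -> str:
    return cell.strip().lower().replace("predicted_", "pred_")


def _parse_count(cell: str, path: Path) -> float:
    try:
        return float(cell)
    except ValueError as exc:
        raise FormatError(f"{path}: confusion-matrix cell {cell!r} is not a number") from exc


def write_confusion_matrix(
    cm: ConfusionMatrix,
    path: str | Path,
    format: str = "auto",
    *,
    metadata: dict | None = None,
) -> None:
    """Write a confusion matrix as JSON or CSV (canonical rows = actual class).

    Fractional (calibrated) matrices are tagged with the ``calibrated`` flag
    so the paired reader accepts them.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    calibrated = any(value != int(value) for value in cm.counts())
    if fmt == "json":
        doc: dict = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
        if calibrated:
            doc["calibrated"] = True
        if metadata:
            doc["metadata"] = metadata
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        if calibrated:
            handle.write("# calibrated: true\n")
        writer.writerow(["", "pred_positive", "pred_negative"])
        writer.writerow(["actual_positive", _fmt_count(cm.tp), _fmt_count(cm.fn)])
        writer.writerow(["actual_negative", _fmt_count(cm.fp), _fmt_count(cm.tn)])


def _fmt_count(value: float) -> str:
    return str(int(value)) if value == int(value) else repr(value)


# ---------------------------------------------------------------------------
# label files

def read_labels(
    path: str | Path,
    positive_label: str | None = None,
    delimiter: str | None = None,
) -> tuple[list[str], list[str]]:
    """Stream a CSV/TSV of (actual, predicted) label pairs.

    The header must name ``actual`` and ``predicted`` columns (any order,
    extra columns ignored).  More than two distinct labels, ragged rows, or
    a ``positive_label`` absent from the observed alphabet are errors.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    actual: list[str] = []
    predicted: list[str] = []
    alphabet: set[str] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty label file")
        columns = [cell.strip().lower() for cell in header]
        try:
            a_col = columns.index("actual")
            p_col = columns.index("predicted")
        except ValueError as exc:
            raise FormatError(
                f"{path}: header must name 'actual' and 'predicted' columns, got {header}"
            ) from exc
        width = len(columns)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row with {len(row)} fields, expected {width}"
                )
            a, p = row[a_col].strip(), row[p_col].strip()
            actual.append(a)
            predicted.append(p)
            alphabet.update((a, p))
            if len(alphabet) > 2:
                raise FormatError(
                    f"{path}:{lineno}: more than two distinct labels: "
                    + ", ".join(sorted(repr(lab) for lab in alphabet))
                )
    if not actual:
        raise FormatError(f"{path}: label file contains no data rows")
    if positive_label is not None and positive_label not in alphabet:
        raise FormatError(
            f"{path}: positive label {positive_label!r} not among observed labels "
            + ", ".join(sorted(repr(lab) for lab in alphabet))
        )
    return actual, predicted


def write_labels(
    actual: Sequence[object], predicted: Sequence[object], path: str | Path
) -> None:
    """Write (actual, predicted) label pairs as a two-column CSV."""
    path = Path(path)
    if len(actual) != len(predicted):
        raise PrevcalError("actual and predicted must have equal length")
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["actual", "predicted"])
        for a, p in zip(actual, predicted):
            writer.writerow([a, p])


# ---------------------------------------------------------------------------
# sweep curves

def write_curve(curve: SweepCurve, path: str | Path) -> None:
    """Export a sweep curve as CSV with ``# metric/sen/spe`` metadata lines."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        handle.write(f"# metric: {curve.metric}\n")
        handle.write(f"# sen: {curve.sen!r}\n")
        handle.write(f"# spe: {curve.spe!r}\n")
        writer = csv.writer(handle)
        writer.writerow(["prevalence", "value"])
        for pre, value in zip(curve.grid, curve.values):
            writer.writerow([repr(pre), repr(value)])


def read_curve(path: str | Path) -> SweepCurve:
    """Read a sweep curve written by :func:`write_curve` (lossless)."""
    path = Path(path)
    meta: dict[str, str] = {}
    grid: list[float] = []
    values: list[float] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header_seen = False
        for row in reader:
            if not row or all(not cell.strip() for cell in row):
                continue
            if row[0].lstrip().startswith("#"):
                text = row[0].lstrip("# ").strip()
                if ":" in text:
                    key, _, value = text.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            if not header_seen:
                if [c.strip().lower() for c in row[:2]] != ["prevalence", "value"]:
                    raise FormatError(f"{path}: expected 'prevalence,value' header, got {row}")
                header_seen = True
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: ragged curve row {row}")
            grid.append(float(row[0]))
            values.append(float(row[1]))
    for key in ("metric", "sen", "spe"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}:' metadata line")
    return SweepCurve(meta["metric"], float(meta["sen"]), float(meta["spe"]), grid, values)


def write_curve_json(curve: SweepCurve, path: str | Path) -> None:
    """Write a sweep curve as a JSON document (schema: curve)."""
    doc = curve.to_dict()
    validate_document(doc, load_schema("curve"))
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_curve_json(path: str | Path) -> SweepCurve:
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    validate_document(doc, load_schema("curve"), str(path))
    return SweepCurve.from_dict(doc)


# ---------------------------------------------------------------------------
# comparison reports

def write_report(report: ComparisonReport, path: str | Path) -> None:
    """Serialise a comparison report to JSON (validated against the schema)."""
    doc = report.to_dict()
    validate_document(doc, load_schema("report"))
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> ComparisonReport:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    validate_document(doc, load_schema("report"), str(path))
    return ComparisonReport.from_dict(doc)


# ---------------------------------------------------------------------------
# scenarios

def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "name": scenario.name,
        "description": scenario.description,
        "expected_flags": list(scenario.expected_flags),
        "runs": [
            {
                "label": label,
                "profile": {
                    "sen": None if is_undefined(profile.sen) else profile.sen,
                    "spe": None if is_undefined(profile.spe) else profile.spe,
                    "pre": profile.pre,
                    "n": profile.n,
                },
            }
            for label, profile in scenario.runs
        ],
    }


def scenario_from_dict(doc: dict) -> Scenario:
    runs = tuple(
        (
            entry["label"],
            PerformanceProfile(
                UNDEFINED if entry["profile"]["sen"] is None else entry["profile"]["sen"],
                UNDEFINED if entry["profile"]["spe"] is None else entry["profile"]["spe"],
                entry["profile"]["pre"],
                entry["profile"]["n"],
            ),
        )
        for entry in doc["runs"]
    )
    return Scenario(
        doc["name"], runs, tuple(doc.get("expected_flags", ())), doc.get("description", "")
    )


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = scenario_to_dict(scenario)
    validate_document(doc, load_schema("scenario"))
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    validate_document(doc, load_schema("scenario"), str(path))
    return scenario_from_dict(doc)
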