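"""Canonical in-memory representation of a Humphrey visual field report.

An :class:`HvfReport` holds the 17 metadata fields printed on a
single-field-analysis report, three 10x10 value grids (raw sensitivity,
total deviation, pattern deviation, in dB) and two 10x10 percentile-icon
grids, plus provenance.  The module also owns the text-level contracts:

* :func:`normalize_field` — raw OCR/DICOM text to canonical typed value
  (dates to ISO, units stripped, signs preserved; unparseable input maps
  to the explicit ``ABSENT`` marker ``None``, never a silent default);
* :func:`serialize_json` / :func:`deserialize_json` — versioned,
  deterministic JSON round-trip;
* :func:`to_delimited` — flat tab-separated export for spreadsheets.

Grid convention: row 0 is the top of the rendered plot, column 0 the
left; indexing is 0-based row-major.  ``"<0"`` (stimulus not seen at
maximal intensity) is a distinct cell state, not a number: collapsing it
to 0 or -1 would silently destroy a clinically meaningful distinction.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, replace

from .layout_registry import METADATA_FIELDS

ABSENT = None

SCHEMA_NAME = "hvfkit-report"
SCHEMA_VERSION = "1.0"

LATERALITIES = ("OD", "OS")
FIELD_SIZES = ("10-2", "24-2", "30-2")
STRATEGIES = ("SITA-Standard", "SITA-Fast", "SITA-Faster")

VALUE_KINDS = ("NUMBER", "BELOW_THRESHOLD", "BLIND_SPOT", "EMPTY")
PERC_KINDS = ("NORMAL", "P5", "P2", "P1", "P05", "BLIND_SPOT", "EMPTY")
VALUE_PLOT_IDS = ("RAW", "TD_VALUE", "PD_VALUE")
PERC_PLOT_IDS = ("TD_PERC", "PD_PERC")


class ParseError(ValueError):
    """JSON document does not conform to the report schema."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class SchemaVersionError(ParseError):
    pass


# --- cells and grids ------------------------------------------------------


@dataclass(frozen=True)
class ValueCell:
    kind: str = "EMPTY"
    value: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"bad value-cell kind {self.kind!r}")
        if self.kind == "NUMBER":
            if self.value is None or not (-40 <= self.value <= 50):
                raise ValueError(f"NUMBER cell out of range: {self.value!r}")
        elif self.value is not None:
            raise ValueError(f"{self.kind} cell must not carry a value")

    @property
    def is_empty(self) -> bool:
        return self.kind == "EMPTY"

    def token(self) -> str:
        """Display token: '24', '-5', '<0', 'BS' or ''. """
        if self.kind == "NUMBER":
            return str(self.value)
        return {"BELOW_THRESHOLD": "<0", "BLIND_SPOT": "BS", "EMPTY": ""}[self.kind]


@dataclass(frozen=True)
class PercentileCell:
    kind: str = "EMPTY"

    def __post_init__(self) -> None:
        if self.kind not in PERC_KINDS:
            raise ValueError(f"bad percentile-cell kind {self.kind!r}")

    @property
    def is_empty(self) -> bool:
        return self.kind == "EMPTY"

    def token(self) -> str:
        if self.kind == "EMPTY":
            return ""
        return "BS" if self.kind == "BLIND_SPOT" else self.kind


@dataclass(frozen=True)
class PlotGrid:
    """10x10 grid of cells for one plot."""

    plot_id: str
    cells: tuple  # 10 rows x 10 cols of ValueCell or PercentileCell

    def __post_init__(self) -> None:
        if self.plot_id not in VALUE_PLOT_IDS + PERC_PLOT_IDS:
            raise ValueError(f"bad plot_id {self.plot_id!r}")
        want = ValueCell if self.plot_id in VALUE_PLOT_IDS else PercentileCell
        rows = tuple(tuple(r) for r in self.cells)
        if len(rows) != 10 or any(len(r) != 10 for r in rows):
            raise ValueError(f"{self.plot_id}: grid must be 10x10")
        for r in rows:
            for c in r:
                if not isinstance(c, want):
                    raise TypeError(
                        f"{self.plot_id}: expected {want.__name__} cells"
                    )
        object.__setattr__(self, "cells", rows)

    @classmethod
    def empty(cls, plot_id: str) -> "PlotGrid":
        cell = ValueCell() if plot_id in VALUE_PLOT_IDS else PercentileCell()
        return cls(plot_id, tuple(tuple(cell for _ in range(10)) for _ in range(10)))

    def __getitem__(self, rc: tuple[int, int]):
        r, c = rc
        return self.cells[r][c]

    def nonempty_positions(self) -> set[tuple[int, int]]:
        return {
            (r, c)
            for r in range(10)
            for c in range(10)
            if not self.cells[r][c].is_empty
        }

    def with_cell(self, r: int, c: int, cell) -> "PlotGrid":
        rows = [list(row) for row in self.cells]
        rows[r][c] = cell
        return PlotGrid(self.plot_id, tuple(tuple(row) for row in rows))


# --- metadata -------------------------------------------------------------


@dataclass(frozen=True)
class HvfMetadata:
    """The 17 metadata fields of a single-field-analysis report.

    ``None`` is the explicit ABSENT marker for any field that is not on
    the report or could not be read.
    """

    name: str | None = ABSENT
    patient_id: str | None = ABSENT
    date_of_birth: _dt.date | None = ABSENT
    test_date: _dt.date | None = ABSENT
    laterality: str | None = ABSENT
    foveal_sensitivity: float | None = ABSENT
    false_positive_rate: str | None = ABSENT
    false_negative_rate: str | None = ABSENT
    fixation_loss: str | None = ABSENT
    test_duration: str | None = ABSENT
    field_size: str | None = ABSENT
    strategy: str | None = ABSENT
    pupil_diameter: float | None = ABSENT
    refraction: str | None = ABSENT
    mean_deviation: float | None = ABSENT
    pattern_standard_deviation: float | None = ABSENT
    vfi: int | None = ABSENT

    def __post_init__(self) -> None:
        if self.laterality not in (ABSENT,) + LATERALITIES:
            raise ValueError(f"bad laterality {self.laterality!r}")
        if self.field_size not in (ABSENT,) + FIELD_SIZES:
            raise ValueError(f"bad field_size {self.field_size!r}")
        if self.strategy not in (ABSENT,) + STRATEGIES:
            raise ValueError(f"bad strategy {self.strategy!r}")

    def get(self, field_id: str):
        if field_id not in METADATA_FIELDS:
            raise KeyError(f"unknown metadata field {field_id!r}")
        return getattr(self, field_id)

    @property
    def fixation_loss_fraction(self) -> tuple[int, int] | None:
        """Parsed (numerator, denominator) of the 'x/y' fixation-loss text."""
        if self.fixation_loss is ABSENT:
            return None
        num, den = self.fixation_loss.split("/")
        return int(num), int(den)

    @property
    def test_duration_seconds(self) -> int | None:
        if self.test_duration is ABSENT:
            return None
        mm, ss = self.test_duration.split(":")
        return int(mm) * 60 + int(ss)


@dataclass(frozen=True)
class HvfReport:
    metadata: HvfMetadata
    raw: PlotGrid
    td_value: PlotGrid
    pd_value: PlotGrid
    td_perc: PlotGrid
    pd_perc: PlotGrid
    source_kind: str = "SYNTHETIC"  # IMAGE | DICOM | JSON | SYNTHETIC
    source: str = ""

    _GRID_IDS = {
        "raw": "RAW",
        "td_value": "TD_VALUE",
        "pd_value": "PD_VALUE",
        "td_perc": "TD_PERC",
        "pd_perc": "PD_PERC",
    }

    def __post_init__(self) -> None:
        for attr, pid in self._GRID_IDS.items():
            grid = getattr(self, attr)
            if grid.plot_id != pid:
                raise ValueError(f"grid {attr} must have plot_id {pid}")
        if self.source_kind not in ("IMAGE", "DICOM", "JSON", "SYNTHETIC"):
            raise ValueError(f"bad source_kind {self.source_kind!r}")

    def grids(self) -> dict[str, PlotGrid]:
        return {pid: getattr(self, a) for a, pid in self._GRID_IDS.items()}

    def consistency_violations(self) -> list[str]:
        """Cross-grid invariants, reported rather than enforced.

        Extraction from a degraded image may legitimately produce a
        report that violates these; they are hard guarantees only for
        reference data (synthetic or DICOM).
        """
        problems = []
        if self.td_value.nonempty_positions() != self.td_perc.nonempty_positions():
            problems.append("td_value and td_perc non-empty cells differ")
        if len(self.raw.nonempty_positions()) < len(self.td_value.nonempty_positions()):
            problems.append("raw grid has fewer non-empty cells than td_value")
        return problems

    def with_provenance(self, kind: str, source: str) -> "HvfReport":
        return replace(self, source_kind=kind, source=source)


# --- field normalization --------------------------------------------------

_DASHES = "−–—"  # minus, en dash, em dash


def _clean(text: str) -> str:
    out = text.strip()
    for d in _DASHES:
        out = out.replace(d, "-")
    return re.sub(r"\s+", " ", out)


def _parse_date(text: str) -> _dt.date | None:
    text = _clean(text)
    m = re.fullmatch(r"(\d{4})-(\d{1,2})-(\d{1,2})", text)
    if m:
        y, mo, d = map(int, m.groups())
    else:
        m = re.fullmatch(r"(\d{1,2})[-/](\d{1,2})[-/](\d{4})", text)
        if not m:
            return ABSENT
        mo, d, y = map(int, m.groups())
    try:
        return _dt.date(y, mo, d)
    except ValueError:
        return ABSENT


def _parse_signed(text: str) -> float | None:
    m = re.search(r"[-+]?\d+(?:\.\d+)?", _clean(text))
    return float(m.group()) if m else ABSENT


def _norm_rate(text: str) -> str | None:
    """False positive/negative rates appear as 'N %' or 'x/y'."""
    text = _clean(text)
    m = re.search(r"(\d+(?:\.\d+)?)\s*%", text)
    if m:
        v = float(m.group(1))
        return f"{int(v)}%" if v == int(v) else f"{v}%"
    m = re.search(r"(\d+)\s*/\s*(\d+)", text)
    if m:
        return f"{m.group(1)}/{m.group(2)}"
    return ABSENT


def normalize_field(field_id: str, raw_text: str):
    """Map raw field text to its canonical typed value (or ``None``).

    Idempotent through :func:`canonical_text`:
    ``normalize(canonical_text(normalize(x))) == normalize(x)``.
    """
    if field_id not in METADATA_FIELDS:
        raise KeyError(f"unknown metadata field {field_id!r}")
    if raw_text is None:
        raise TypeError("raw_text must be text, not None")
    text = _clean(raw_text)
    if not text:
        return ABSENT

    if field_id in ("name", "refraction"):
        out = text.upper()
        # refraction must look like an Rx (contain a digit); a name must not
        # be pure punctuation
        if field_id == "refraction" and not re.search(r"\d", out):
            return ABSENT
        if field_id == "name" and not re.search(r"[A-Z0-9]", out):
            return ABSENT
        return out
    if field_id == "patient_id":
        m = re.fullmatch(r"[A-Za-z0-9][A-Za-z0-9-]*", text)
        return m.group().upper() if m else ABSENT
    if field_id in ("date_of_birth", "test_date"):
        return _parse_date(text)
    if field_id == "laterality":
        key = text.upper().rstrip(".")
        return {
            "OD": "OD", "RIGHT": "OD", "R": "OD",
            "OS": "OS", "LEFT": "OS", "L": "OS",
        }.get(key, ABSENT)
    if field_id in ("foveal_sensitivity", "mean_deviation", "pupil_diameter",
                    "pattern_standard_deviation"):
        if field_id == "foveal_sensitivity" and (
            text.upper() in ("OFF", "N/A") or text.startswith("<")
        ):
            # "<0" is a distinct below-threshold state, not the number 0
            return ABSENT
        v = _parse_signed(text)
        if v is ABSENT:
            return ABSENT
        if field_id == "pattern_standard_deviation" and v < 0:
            return ABSENT
        if field_id == "pupil_diameter" and v <= 0:
            return ABSENT
        return v
    if field_id in ("false_positive_rate", "false_negative_rate"):
        return _norm_rate(text)
    if field_id == "fixation_loss":
        m = re.search(r"(\d+)\s*/\s*(\d+)", text)
        return f"{m.group(1)}/{m.group(2)}" if m else ABSENT
    if field_id == "test_duration":
        m = re.search(r"(\d{1,2}):(\d{2})(?!\d)", text)
        if not m or int(m.group(2)) >= 60:
            return ABSENT
        return f"{int(m.group(1)):02d}:{m.group(2)}"
    if field_id == "field_size":
        m = re.search(r"(10|24|30)\s*-\s*2", text)
        return f"{m.group(1)}-2" if m else ABSENT
    if field_id == "strategy":
        key = re.sub(r"[\s-]", "", text.upper())
        if "SITAFASTER" in key:
            return "SITA-Faster"
        if "SITAFAST" in key:
            return "SITA-Fast"
        if "SITASTANDARD" in key:
            return "SITA-Standard"
        return ABSENT
    if field_id == "vfi":
        m = re.search(r"(\d+(?:\.\d+)?)\s*%?", text)
        if not m:
            return ABSENT
        v = float(m.group(1))
        return int(round(v)) if 0 <= v <= 100 else ABSENT
    raise AssertionError(field_id)


def canonical_text(field_id: str, value) -> str:
    """Canonical display text for a normalized value ('' for ABSENT)."""
    if field_id not in METADATA_FIELDS:
        raise KeyError(f"unknown metadata field {field_id!r}")
    if value is ABSENT:
        return ""
    if isinstance(value, _dt.date):
        return value.isoformat()
    if field_id == "vfi":
        return f"{value}%"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


# --- JSON serialization ---------------------------------------------------

_VALUE_ENC = {"BELOW_THRESHOLD": "<0", "BLIND_SPOT": "BS"}


def _encode_value_cell(cell: ValueCell):
    if cell.kind == "NUMBER":
        return cell.value
    if cell.kind == "EMPTY":
        return None
    return _VALUE_ENC[cell.kind]


def _decode_value_cell(obj, path: str) -> ValueCell:
    if obj is None:
        return ValueCell()
    if isinstance(obj, bool):
        raise ParseError(path, f"bad value cell {obj!r}")
    if isinstance(obj, int):
        try:
            return ValueCell("NUMBER", obj)
        except ValueError as e:
            raise ParseError(path, str(e)) from None
    if obj == "<0":
        return ValueCell("BELOW_THRESHOLD")
    if obj == "BS":
        return ValueCell("BLIND_SPOT")
    raise ParseError(path, f"bad value cell {obj!r}")


def _encode_perc_cell(cell: PercentileCell):
    if cell.kind == "EMPTY":
        return None
    return "BS" if cell.kind == "BLIND_SPOT" else cell.kind


def _decode_perc_cell(obj, path: str) -> PercentileCell:
    if obj is None:
        return PercentileCell()
    if obj == "BS":
        return PercentileCell("BLIND_SPOT")
    if obj in PERC_KINDS and obj not in ("BLIND_SPOT", "EMPTY"):
        return PercentileCell(obj)
    raise ParseError(path, f"bad percentile cell {obj!r}")


def _metadata_to_json(md: HvfMetadata) -> dict:
    out = {}
    for fid in METADATA_FIELDS:
        v = md.get(fid)
        out[fid] = v.isoformat() if isinstance(v, _dt.date) else v
    return out


def _metadata_from_json(obj: dict, path: str) -> HvfMetadata:
    if not isinstance(obj, dict):
        raise ParseError(path, "metadata must be an object")
    unknown = set(obj) - set(METADATA_FIELDS)
    if unknown:
        raise ParseError(path, f"unknown metadata fields {sorted(unknown)}")
    kwargs = {}
    for fid in METADATA_FIELDS:
        v = obj.get(fid, ABSENT)
        if v is ABSENT:
            continue
        if fid in ("date_of_birth", "test_date"):
            d = _parse_date(str(v))
            if d is ABSENT:
                raise ParseError(f"{path}.{fid}", f"bad date {v!r}")
            v = d
        kwargs[fid] = v
    try:
        return HvfMetadata(**kwargs)
    except (ValueError, TypeError) as e:
        raise ParseError(path, str(e)) from None


def serialize_json(report: HvfReport) -> str:
    """Deterministic, versioned JSON text for a report."""
    doc = {
        "schema": SCHEMA_NAME,
        "schema_version": SCHEMA_VERSION,
        "provenance": {"kind": report.source_kind, "source": report.source},
        "metadata": _metadata_to_json(report.metadata),
        "plots": {
            "raw": [[_encode_value_cell(c) for c in row] for row in report.raw.cells],
            "td_value": [[_encode_value_cell(c) for c in row]
                         for row in report.td_value.cells],
            "pd_value": [[_encode_value_cell(c) for c in row]
                         for row in report.pd_value.cells],
            "td_perc": [[_encode_perc_cell(c) for c in row]
                        for row in report.td_perc.cells],
            "pd_perc": [[_encode_perc_cell(c) for c in row]
                        for row in report.pd_perc.cells],
        },
    }
    return json.dumps(doc, indent=1, ensure_ascii=True)


def deserialize_json(text: str) -> HvfReport:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError("$", f"not valid JSON: {e}") from None
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA_NAME:
        raise ParseError("$.schema", f"not a {SCHEMA_NAME} document")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaVersionError(
            "$.schema_version",
            f"unsupported version {doc.get('schema_version')!r} "
            f"(expected {SCHEMA_VERSION})",
        )
    md = _metadata_from_json(doc.get("metadata", {}), "$.metadata")
    plots = doc.get("plots")
    if not isinstance(plots, dict):
        raise ParseError("$.plots", "missing plots object")

    def grid(key: str, pid: str, decode) -> PlotGrid:
        rows = plots.get(key)
        path = f"$.plots.{key}"
        if not isinstance(rows, list) or len(rows) != 10:
            raise ParseError(path, "grid must have exactly 10 rows")
        cells = []
        for r, row in enumerate(rows):
            if not isinstance(row, list) or len(row) != 10:
                raise ParseError(f"{path}[{r}]", "row must have exactly 10 cells")
            cells.append(tuple(
                decode(v, f"{path}[{r}][{c}]") for c, v in enumerate(row)
            ))
        return PlotGrid(pid, tuple(cells))

    prov = doc.get("provenance", {})
    kind = prov.get("kind", "JSON")
    if kind not in ("IMAGE", "DICOM", "JSON", "SYNTHETIC"):
        raise ParseError("$.provenance.kind", f"bad source kind {kind!r}")
    return HvfReport(
        metadata=md,
        raw=grid("raw", "RAW", _decode_value_cell),
        td_value=grid("td_value", "TD_VALUE", _decode_value_cell),
        pd_value=grid("pd_value", "PD_VALUE", _decode_value_cell),
        td_perc=grid("td_perc", "TD_PERC", _decode_perc_cell),
        pd_perc=grid("pd_perc", "PD_PERC", _decode_perc_cell),
        source_kind=kind,
        source=prov.get("source", ""),
    )


# --- delimited export -----------------------------------------------------

_GRID_KEYS = ("raw", "td_value", "pd_value", "td_perc", "pd_perc")


def delimited_header() -> list[str]:
    cols = ["source_kind", "source", *METADATA_FIELDS]
    for key in _GRID_KEYS:
        cols += [f"{key}_r{r}c{c}" for r in range(10) for c in range(10)]
    return cols


def to_delimited(reports: list[HvfReport]) -> str:
    """Tab-delimited table, one row per report (UNIX newlines, UTF-8).

    Metadata columns use the fixed 17-field order; plot cells are
    flattened row-major as ``<grid>_r<row>c<col>``; EMPTY cells are blank.
    """
    if not reports:
        raise ValueError("need at least one report")
    lines = ["\t".join(delimited_header())]
    for rep in reports:
        row = [rep.source_kind, rep.source]
        row += [canonical_text(fid, rep.metadata.get(fid)) for fid in METADATA_FIELDS]
        for key in _GRID_KEYS:
            grid = getattr(rep, key)
            row += [grid.cells[r][c].token() for r in range(10) for c in range(10)]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
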