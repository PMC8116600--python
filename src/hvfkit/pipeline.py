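"""End-to-end orchestration: file dispatch, full-page extraction, batches.

``extract_file`` dispatches on content (magic bytes, not extension):
PNG pages go through layout detection, metadata OCR and plot/cell
recognition; DICOM OPV files through the tag-map reader; JSON through
the schema deserializer.  Recognition failures inside a page degrade to
warnings (the affected cells/fields stay EMPTY/ABSENT) rather than
aborting the report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dicom_ingest
from .cell_recognition import (
    UnreadableCell,
    classify_percentile_cell,
    classify_value_cell,
)
from .data_model import (
    ABSENT,
    HvfReport,
    ParseError,
    PlotGrid,
    deserialize_json,
    serialize_json,
    to_delimited,
)
from .glyphs import TemplateSet
from .layout_registry import (
    LayoutSpec,
    METADATA_FIELDS,
    UnsupportedLayout,
    detect_layout,
)
from .metadata_extraction import extract_metadata
from .plot_extraction import PlotNotFound, binarize, locate_plot, split_grid
from .synthetic import load_png


class UnreadableFile(ValueError):
    """Input is none of PNG, DICOM or report JSON."""


@dataclass
class ExtractionRecord:
    source: str
    report: HvfReport
    warnings: list[str] = field(default_factory=list)
    timing: float = 0.0


def extract_report(
    image: np.ndarray,
    layout: LayoutSpec,
    templates: TemplateSet | None = None,
) -> tuple[HvfReport, list[str]]:
    """Run the full image pipeline for a page known to match ``layout``."""
    templates = templates or TemplateSet.canonical(
        layout.version, layout.glyph_scale
    )
    warnings: list[str] = []
    ink = binarize(image)
    metadata = extract_metadata(ink, layout)
    for fid in METADATA_FIELDS:
        if metadata.get(fid) is ABSENT:
            warnings.append(f"metadata field {fid} is ABSENT")

    grids: dict[str, PlotGrid] = {}
    for pid in ("RAW", "TD_VALUE", "PD_VALUE", "TD_PERC", "PD_PERC"):
        grid = PlotGrid.empty(pid)
        try:
            geom = locate_plot(ink, layout, pid)
            cells = split_grid(ink, geom)
        except (PlotNotFound, ValueError) as e:
            warnings.append(f"plot {pid}: {e}")
            grids[pid] = grid
            continue
        for idx, cell in enumerate(cells):
            r, c = divmod(idx, 10)
            if pid in ("TD_PERC", "PD_PERC"):
                out = classify_percentile_cell(cell, templates)
                if not out.is_empty:
                    grid = grid.with_cell(r, c, out)
            else:
                try:
                    out = classify_value_cell(cell, templates, coords=(r, c))
                except UnreadableCell as e:
                    warnings.append(f"plot {pid}: {e}")
                    continue
                if not out.is_empty:
                    grid = grid.with_cell(r, c, out)
        grids[pid] = grid

    report = HvfReport(
        metadata=metadata,
        raw=grids["RAW"],
        td_value=grids["TD_VALUE"],
        pd_value=grids["PD_VALUE"],
        td_perc=grids["TD_PERC"],
        pd_perc=grids["PD_PERC"],
        source_kind="IMAGE",
        source="",
    )
    warnings.extend(f"consistency: {p}" for p in report.consistency_violations())
    return report, warnings


def _sniff(path: Path) -> str:
    with open(path, "rb") as f:
        head = f.read(512)
    if head.startswith(b"\x89PNG\r\n\x1a\n"):
        return "png"
    if len(head) >= 132 and head[128:132] == b"DICM":
        return "dicom"
    if head.lstrip()[:1] == b"{":
        return "json"
    raise UnreadableFile(f"{path}: not a PNG, DICOM or report JSON file")


def extract_file(
    path: str | Path,
    layout_file: str | Path | None = None,
    templates: TemplateSet | None = None,
) -> ExtractionRecord:
    """Extract one input file (PNG report image, OPV DICOM or JSON)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    kind = _sniff(path)
    t0 = time.perf_counter()
    warnings: list[str] = []
    if kind == "png":
        image = load_png(path)
        h, w = image.shape
        if layout_file is not None:
            layout = LayoutSpec.from_file(layout_file)
        else:
            layout = detect_layout(w, h)
        report, warnings = extract_report(image, layout, templates)
        report = report.with_provenance("IMAGE", str(path))
    elif kind == "dicom":
        report = dicom_ingest.read_opv(path).with_provenance("DICOM", str(path))
    else:
        report = deserialize_json(path.read_text())
        report = report.with_provenance(report.source_kind, str(path))
    return ExtractionRecord(
        source=str(path),
        report=report,
        warnings=warnings,
        timing=time.perf_counter() - t0,
    )


def run_batch(directory: str | Path, out: str | Path,
              layout_file: str | Path | None = None) -> dict:
    """Extract every readable file in a directory (lexicographic order).

    Writes ``<stem>.json`` per input plus a combined ``batch.tsv``.
    Per-file failures are tallied, not fatal.  Deterministic across
    reruns.
    """
    directory, out = Path(directory), Path(out)
    if not directory.is_dir():
        raise NotADirectoryError(str(directory))
    out.mkdir(parents=True, exist_ok=True)
    counts = {"processed": 0, "failed": 0, "warnings": 0}
    reports, failures = [], []
    for path in sorted(p for p in directory.iterdir() if p.is_file()):
        try:
            rec = extract_file(path, layout_file=layout_file)
        except (UnreadableFile, UnsupportedLayout, ParseError,
                dicom_ingest.DicomParseError, dicom_ingest.NotOpv) as e:
            counts["failed"] += 1
            failures.append(f"{path.name}: {e}")
            continue
        counts["processed"] += 1
        counts["warnings"] += len(rec.warnings)
        (out / f"{path.stem}.json").write_text(serialize_json(rec.report))
        reports.append(rec.report)
    if reports:
        (out / "batch.tsv").write_text(to_delimited(reports))
    if failures:
        (out / "failures.txt").write_text("\n".join(failures) + "\n")
    return counts


def run_validation(extracted_dir: str | Path, reference_dir: str | Path) -> dict:
    """Compare extraction outputs against reference data, paired by stem.

    References may be OPV DICOM or report JSON.  Returns a dictionary
    with per-category error summaries (metadata / value plots /
    percentile plots) over all paired reports, plus any unpaired stems.
    The caller batches one report layout per directory when a
    per-layout breakdown is wanted.
    """
    from .comparison import compare_reports, summarize

    extracted_dir, reference_dir = Path(extracted_dir), Path(reference_dir)

    def index(d: Path) -> dict:
        # prefer structured data (.json/.dcm) over an image with the same stem
        files = sorted((p for p in d.iterdir()
                        if p.is_file() and p.suffix != ".tsv"
                        and p.stem != "failures"),
                       key=lambda p: (p.suffix == ".png", p.name))
        out: dict = {}
        for p in files:
            out.setdefault(p.stem, p)
        return out

    ext = index(extracted_dir)
    ref = index(reference_dir)
    stems = sorted(set(ext) & set(ref))
    unpaired = sorted(set(ext) ^ set(ref))
    by_cat: dict[str, list] = {"metadata": [], "value": [], "percentile": []}
    for stem in stems:
        e = extract_file(ext[stem]).report
        r = extract_file(ref[stem]).report
        outcomes = compare_reports(e, r)
        for cat in by_cat:
            by_cat[cat].append(outcomes[cat])
    result = {"n_pairs": len(stems), "unpaired": unpaired}
    if stems:
        result["summaries"] = {
            cat: summarize(groups).to_dict() for cat, groups in by_cat.items()
        }
    return result
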