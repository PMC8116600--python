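"""Metadata OCR and label anchoring.

Each of the 17 metadata fields has its own crop region (per-field
cropping keeps a garbled line in one region from contaminating another
field).  The crop is OCR'd by the same template-matching engine used on
plot cells, but over the full shipped character set; the resulting
lines are anchored to the field by fuzzy label matching (normalized
Levenshtein ratio against the anchor table's label variants) and the
value is pulled out with the anchor's regular expression.  A field
whose region yields no text, or whose label similarity stays below the
anchor threshold, is ABSENT — never fabricated.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import scipy.ndimage as ndi

from .cell_recognition import match_raster
from .data_model import ABSENT, HvfMetadata, normalize_field
from .glyphs import FONT_RASTERS, raster_to_array
from .layout_registry import LayoutSpec, METADATA_FIELDS, region_pixels
from .plot_extraction import binarize


@dataclass(frozen=True)
class LabelAnchor:
    field_id: str
    label_variants: tuple[str, ...]
    value_pattern: str
    fuzzy_threshold: float = 85.0

    def __post_init__(self) -> None:
        if not self.label_variants:
            raise ValueError(f"{self.field_id}: need at least one label variant")
        if not (0 <= self.fuzzy_threshold <= 100):
            raise ValueError(f"{self.field_id}: threshold must be in [0, 100]")


@lru_cache(maxsize=1)
def load_anchors() -> dict[str, LabelAnchor]:
    doc = json.loads((resources.files("hvfkit.config") / "anchors.json").read_text())
    return {
        fid: LabelAnchor(
            field_id=fid,
            label_variants=tuple(spec["labels"]),
            value_pattern=spec["pattern"],
            fuzzy_threshold=spec.get("threshold", 85),
        )
        for fid, spec in doc.items()
    }


def levenshtein_ratio(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 100] (case-sensitive)."""
    if a == b:
        return 100.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return 100.0 * (1.0 - prev[lb] / max(la, lb))


# --- character OCR --------------------------------------------------------

_CHAR_ORDER = sorted(FONT_RASTERS)


@lru_cache(maxsize=1)
def _char_templates() -> dict[str, np.ndarray]:
    return {ch: raster_to_array(FONT_RASTERS[ch]) for ch in _CHAR_ORDER}


_EIGHT = np.ones((3, 3), dtype=int)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where a 1-D boolean mask is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _merge_close(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for r in runs:
        if out and r[0] - out[-1][1] < gap:
            out[-1] = (out[-1][0], r[1])
        else:
            out.append(r)
    return out


def _read_line(band: np.ndarray, scale: int) -> str:
    """Segment one line band into characters and spaces, and match them."""
    col_ink = band.any(axis=0)
    boxes = _runs(col_ink)
    if not boxes:
        return ""
    templates = _char_templates()
    min_area = max(2, scale * scale)
    text, prev_end = [], None
    for x0, x1 in boxes:
        sub = band[:, x0:x1]
        rows = np.flatnonzero(sub.any(axis=1))
        sub = sub[rows[0]:rows[-1] + 1]
        if int(sub.sum()) < min_area:
            continue
        # monospaced geometry: intra-word bbox gaps stay below ~4.5x the
        # glyph scale, word spaces above ~7x; 5.5x splits them cleanly
        if prev_end is not None and x0 - prev_end >= 5.5 * scale:
            text.append(" ")
        text.append(match_raster(sub, templates, _CHAR_ORDER).best_id)
        prev_end = x1
    return "".join(text).strip()


def ocr_region(
    image: np.ndarray,
    box: tuple[int, int, int, int],
    glyph_scale: int | None = None,
) -> list[str]:
    """Recognize the text lines inside a pixel box, top to bottom.

    ``image`` is a grayscale page or a pre-binarized ink mask; ``box``
    must lie inside it.  Returns one string per line; an empty region
    yields an empty list.
    """
    ink = binarize(np.asarray(image))
    H, W = ink.shape
    x0, y0, x1, y1 = box
    if not (0 <= x0 < x1 <= W and 0 <= y0 < y1 <= H):
        raise ValueError(f"box {box} outside image {W}x{H}")
    crop = ink[y0:y1, x0:x1]
    if not crop.any():
        return []
    scale = glyph_scale
    bands = _runs(crop.any(axis=1))
    if scale is None:
        scale = max(1, round(max(b1 - b0 for b0, b1 in bands) / 7))
    bands = _merge_close(bands, gap=max(2, scale))
    lines = []
    for b0, b1 in bands:
        line = _read_line(crop[b0:b1], scale)
        if line:
            lines.append(line)
    return lines


# --- anchoring ------------------------------------------------------------


def _label_value(line: str) -> tuple[str, str]:
    """Split a printed line into its label part and value part."""
    if ":" in line:
        label, value = line.split(":", 1)
        return label.strip(), value.strip()
    return line.strip(), line.strip()


def anchor_field(lines: list[str], anchor: LabelAnchor):
    """Pick the line whose label best matches the anchor and extract the
    raw value text; ABSENT when nothing clears the fuzzy threshold.

    Case- and surrounding-whitespace-insensitive; on ties the first line
    wins.
    """
    best_sim, best_value = -1.0, ABSENT
    for line in lines:
        label, value = _label_value(line)
        sim = max(
            levenshtein_ratio(label.casefold().strip(), v.casefold())
            for v in anchor.label_variants
        )
        if sim > best_sim:
            best_sim, best_value = sim, value
    if best_sim < anchor.fuzzy_threshold or best_value is ABSENT:
        return ABSENT
    m = re.search(anchor.value_pattern, best_value, flags=re.IGNORECASE)
    return m.group(0).strip() if m else ABSENT


def extract_metadata(
    image: np.ndarray,
    layout: LayoutSpec,
    anchors: dict[str, LabelAnchor] | None = None,
) -> HvfMetadata:
    """OCR all 17 metadata regions of a page and normalize the fields."""
    anchors = anchors or load_anchors()
    ink = binarize(np.asarray(image))
    H, W = ink.shape
    values = {}
    for fid in METADATA_FIELDS:
        box = region_pixels(layout, fid, W, H)
        lines = ocr_region(ink, box, layout.glyph_scale)
        raw = anchor_field(lines, anchors[fid])
        if raw is ABSENT:
            continue
        v = normalize_field(fid, raw)
        if v is not ABSENT:
            values[fid] = v
    return HvfMetadata(**values)
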