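"""Template-matching recognition of plot cells.

A value cell holds a 1-3 glyph token ("24", "-5", "<0"), a blind-spot
triangle, or nothing; a percentile cell holds one of five icon textures.
Recognition is classical template matching: connected components are
segmented, size-normalized against the reference rasters and scored by
normalized cross-correlation.  There is no learned model — determinism
and auditability are the point.

Robustness details that matter in practice:

* a minus sign is recognized structurally (wide, flat, well-filled)
  before any correlation, because a thin dash correlates poorly and a
  dropped minus sign silently flips the sign of a deviation value;
* residual fragments of the plot axes (thin full-height/width strips at
  a cell border that survive axis masking on degraded images) are
  discarded before matching;
* fragments of the blind-spot triangle that intrude into a neighbouring
  cell are stripped before digit assembly (`strip_triangle`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .data_model import PercentileCell, ValueCell
from .glyphs import ICON_IDS, TemplateSet

#: fixed tie-break orders (first wins on equal scores)
GLYPH_ORDER = [str(d) for d in range(10)] + ["MINUS", "LT", "TRIANGLE"]
ICON_ORDER = list(ICON_IDS) + ["TRIANGLE"]

#: ink fraction below which a cell is considered empty
EMPTINESS_THRESHOLD = 0.005
#: horizontal-overlap fraction above which two components are one glyph
MERGE_OVERLAP = 0.7
#: minimum similarity for a component to be stripped as a triangle (fragment)
TRIANGLE_STRIP_THRESHOLD = 0.75


class UnreadableCell(ValueError):
    """A cell whose ink could not be parsed into a legal token."""

    def __init__(self, token: str, coords: tuple[int, int] | None = None):
        self.token = token
        self.coords = coords
        at = f" at {coords}" if coords is not None else ""
        super().__init__(f"unparseable cell token {token!r}{at}")


@dataclass(frozen=True)
class MatchResult:
    best_id: str
    score: float
    runner_up_margin: float


# --- similarity -----------------------------------------------------------


def _crop_to_ink(a: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(a.any(axis=1))
    cols = np.flatnonzero(a.any(axis=0))
    return a[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def _resize_nn(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = a.shape
    ri = (np.arange(shape[0]) * h // shape[0]).clip(0, h - 1)
    ci = (np.arange(shape[1]) * w // shape[1]).clip(0, w - 1)
    return a[np.ix_(ri, ci)]


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two binary rasters, in [0, 1].

    Both rasters are cropped to their ink bounding boxes and
    nearest-neighbour resized to a common (elementwise max) shape, so
    the measure is scale-robust and symmetric; 1.0 iff identical after
    normalization.
    """
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    if not a.any() or not b.any():
        raise ValueError("similarity of an empty raster is undefined")
    a, b = _crop_to_ink(a), _crop_to_ink(b)
    shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
    ar = _resize_nn(a, shape)
    br = _resize_nn(b, shape)
    if np.array_equal(ar, br):  # identical after normalization: exactly 1
        return 1.0
    af = ar.astype(np.float64).ravel()
    bf = br.astype(np.float64).ravel()
    am, bm = af - af.mean(), bf - bf.mean()
    na, nb = np.linalg.norm(am), np.linalg.norm(bm)
    if na == 0 or nb == 0:  # one raster uniform after resize
        return 1.0 if np.array_equal(af, bf) else 0.0
    return float(np.clip((am @ bm) / (na * nb) + 1.0, 0.0, 2.0) / 2.0)


def _aspect_factor(a: np.ndarray, b: np.ndarray) -> float:
    """Penalize candidates whose ink aspect ratio disagrees with the query.

    Bounding-box size normalization makes NCC blind to shape extremes
    (a dot and a dash both normalize to a solid block); the factor
    sqrt(min/max of the two aspect ratios) restores that cue without
    affecting same-shaped candidates.
    """
    ca, cb = _crop_to_ink(a), _crop_to_ink(b)
    ra = ca.shape[1] / ca.shape[0]
    rb = cb.shape[1] / cb.shape[0]
    return float(np.sqrt(min(ra, rb) / max(ra, rb)))


def match_raster(
    raster: np.ndarray, candidates: dict[str, np.ndarray], order: list[str]
) -> MatchResult:
    scores = [(cid, similarity(raster, candidates[cid])
               * _aspect_factor(raster, candidates[cid]))
              for cid in order if cid in candidates]
    scores.sort(key=lambda t: -t[1])  # stable: preserves `order` on ties
    best_id, best = scores[0]
    margin = best - scores[1][1] if len(scores) > 1 else best
    return MatchResult(best_id=best_id, score=best, runner_up_margin=margin)


# --- component segmentation -----------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class _Component:
    raster: np.ndarray  # cropped to its bounding box
    box: tuple[int, int, int, int]  # (x0, y0, x1, y1) within the cell


def _components(cell: np.ndarray) -> list[_Component]:
    labels, n = ndi.label(cell, structure=_EIGHT)
    comps = []
    for sl in ndi.find_objects(labels):
        if sl is None:
            continue
        sub = labels[sl] > 0
        comps.append(_Component(
            raster=sub,
            box=(sl[1].start, sl[0].start, sl[1].stop, sl[0].stop),
        ))
    comps.sort(key=lambda c: (c.box[0], c.box[1]))
    return comps


def _filter_noise(comps: list[_Component], cell_shape) -> list[_Component]:
    h, w = cell_shape
    min_area = max(4, int(0.002 * h * w))
    out = []
    for c in comps:
        if int(c.raster.sum()) < min_area:
            continue
        x0, y0, x1, y1 = c.box
        cw, ch = x1 - x0, y1 - y0
        # axis residue: thin strip spanning nearly the whole cell at a border
        if cw <= 2 and ch >= 0.8 * h and (x0 <= 1 or x1 >= w - 1):
            continue
        if ch <= 2 and cw >= 0.8 * w and (y0 <= 1 or y1 >= h - 1):
            continue
        out.append(c)
    return out


def _merge_fragments(comps: list[_Component], cell: np.ndarray) -> list[_Component]:
    """Merge components overlapping horizontally by >70% (broken glyphs)."""
    merged: list[_Component] = []
    for c in comps:
        if merged:
            p = merged[-1]
            lo, hi = max(p.box[0], c.box[0]), min(p.box[2], c.box[2])
            overlap = hi - lo
            width = min(p.box[2] - p.box[0], c.box[2] - c.box[0])
            if width > 0 and overlap / width > MERGE_OVERLAP:
                x0 = min(p.box[0], c.box[0])
                y0 = min(p.box[1], c.box[1])
                x1 = max(p.box[2], c.box[2])
                y1 = max(p.box[3], c.box[3])
                merged[-1] = _Component(
                    raster=cell[y0:y1, x0:x1].copy(), box=(x0, y0, x1, y1)
                )
                continue
        merged.append(c)
    return merged


def _is_structural_minus(c: _Component) -> bool:
    x0, y0, x1, y1 = c.box
    w, h = x1 - x0, y1 - y0
    return w >= 2 * h and c.raster.mean() > 0.6


def _segment(cell: np.ndarray) -> list[_Component]:
    comps = _filter_noise(_components(np.asarray(cell, bool)), cell.shape)
    return _merge_fragments(comps, np.asarray(cell, bool))


# --- classification -------------------------------------------------------


def _glyph_candidates(templates: TemplateSet) -> tuple[dict, list[str]]:
    """Glyph templates plus half-triangle rasters.

    The blind-spot triangle often intrudes on a neighbouring cell as a
    *fragment*; a half triangle resembles a digit more than it resembles
    the whole icon, so the halves are matched explicitly.  Any id
    beginning with TRIANGLE is treated as triangle ink downstream.
    """
    tri = templates.glyphs["TRIANGLE"]
    half = tri.shape[1] // 2
    cands = dict(templates.glyphs)
    cands["TRIANGLE_L"] = tri[:, :half]
    cands["TRIANGLE_R"] = tri[:, half:]
    return cands, GLYPH_ORDER + ["TRIANGLE_L", "TRIANGLE_R"]


def _is_triangle(glyph_id: str) -> bool:
    return glyph_id.startswith("TRIANGLE")


def _score_component(c: _Component, templates: TemplateSet) -> tuple[str, float]:
    if _is_structural_minus(c):
        return "MINUS", 1.0
    cands, order = _glyph_candidates(templates)
    m = match_raster(c.raster, cands, order)
    return m.best_id, m.score


def _split_at_valley(c: _Component):
    """Split a component at its weakest interior column, or None."""
    profile = c.raster.sum(axis=0)
    w = len(profile)
    if w < 6:
        return None
    lo, hi = w // 4, w - w // 4
    i = lo + int(np.argmin(profile[lo:hi]))
    halves = []
    for cols in (slice(0, i), slice(i, w)):
        sub = c.raster[:, cols]
        if not sub.any():
            return None
        rows = np.flatnonzero(sub.any(axis=1))
        ccols = np.flatnonzero(sub.any(axis=0))
        sub = sub[rows[0]:rows[-1] + 1, ccols[0]:ccols[-1] + 1]
        x0 = c.box[0] + cols.start + ccols[0]
        y0 = c.box[1] + rows[0]
        halves.append(_Component(
            raster=sub, box=(x0, y0, x0 + sub.shape[1], y0 + sub.shape[0])
        ))
    return halves


#: below this match score a wide component is suspected of being two
#: blur-merged glyphs and a projection split is attempted
SPLIT_SCORE = 0.85


def _classify_components(
    comps: list[_Component], templates: TemplateSet, depth: int = 0
) -> list[tuple[_Component, str, float]]:
    """Match components, splitting low-confidence wide blobs (merged
    glyphs on degraded renders) when the halves match better whole."""
    out = []
    for c in comps:
        gid, score = _score_component(c, templates)
        w, h = c.box[2] - c.box[0], c.box[3] - c.box[1]
        if depth < 3 and score < SPLIT_SCORE and w > 1.15 * h:
            halves = _split_at_valley(c)
            if halves is not None:
                scored = [_score_component(p, templates) for p in halves]
                if min(s for _, s in scored) > score:
                    out.extend(_classify_components(halves, templates, depth + 1))
                    continue
        out.append((c, gid, score))
    return out


def strip_triangle(cell: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """Remove blind-spot-triangle components (or fragments) from a cell.

    Idempotent; used on raw-plot cells where the triangle icon intrudes
    on a neighbouring value.
    """
    cell = np.asarray(cell, bool).copy()
    cands, order = _glyph_candidates(templates)
    for c in _segment(cell):
        m = match_raster(c.raster, cands, order)
        if _is_triangle(m.best_id) and m.score >= TRIANGLE_STRIP_THRESHOLD:
            x0, y0, x1, y1 = c.box
            cell[y0:y1, x0:x1][c.raster] = False
    return cell


_CHAR = {**{str(d): str(d) for d in range(10)}, "MINUS": "-", "LT": "<",
         "TRIANGLE": "T"}


def classify_value_cell(
    cell: np.ndarray,
    templates: TemplateSet,
    coords: tuple[int, int] | None = None,
) -> ValueCell:
    """Classify one value-plot cell raster.

    Triangle-only ink is the blind spot; triangle fragments next to a
    value are stripped before the token is assembled.  An ink pattern
    that parses to nothing legal raises :class:`UnreadableCell` rather
    than guessing.
    """
    cell = np.asarray(cell, bool)
    comps = _segment(cell)
    filtered_ink = sum(int(c.raster.sum()) for c in comps)
    if not comps or filtered_ink < EMPTINESS_THRESHOLD * cell.size:
        return ValueCell("EMPTY")
    classified = _classify_components(comps, templates)
    if all(_is_triangle(g) for _, g, _ in classified):
        return ValueCell("BLIND_SPOT")
    # drop triangle fragments intruding from a neighbouring blind spot;
    # collapse repeated MINUS components (a snapped bar is still one sign)
    token = ""
    for _, g, _ in classified:
        if _is_triangle(g):
            continue
        ch = _CHAR[g]
        if ch == "-" and token.endswith("-"):
            continue
        token += ch
    if token == "<0":
        return ValueCell("BELOW_THRESHOLD")
    if token and (token.lstrip("-").isdigit()) and len(token.lstrip("-")) <= 2 \
            and not token.startswith("--"):
        v = int(token)
        if -40 <= v <= 50:
            return ValueCell("NUMBER", v)
    raise UnreadableCell(token, coords)


def classify_percentile_cell(
    cell: np.ndarray, templates: TemplateSet
) -> PercentileCell:
    """Classify one percentile-plot cell into its icon class (or EMPTY).

    Never raises: the cell's whole ink pattern is matched as one raster
    against the five icons plus the triangle, argmax wins with a fixed
    tie-break order.
    """
    cell = np.asarray(cell, bool)
    comps = _segment(cell)
    filtered_ink = sum(int(c.raster.sum()) for c in comps)
    if not comps or filtered_ink < EMPTINESS_THRESHOLD * cell.size:
        return PercentileCell("EMPTY")
    x0 = min(c.box[0] for c in comps)
    y0 = min(c.box[1] for c in comps)
    x1 = max(c.box[2] for c in comps)
    y1 = max(c.box[3] for c in comps)
    union = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    for c in comps:
        cx0, cy0, cx1, cy1 = c.box
        union[cy0 - y0:cy1 - y0, cx0 - x0:cx1 - x0] |= c.raster
    cands = {**templates.icons, "TRIANGLE": templates.glyphs["TRIANGLE"]}
    m = match_raster(union, cands, ICON_ORDER)
    if m.best_id == "TRIANGLE":
        return PercentileCell("BLIND_SPOT")
    return PercentileCell(m.best_id)
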