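"""Synthetic report generator: ground-truth data, page rendering, noise.

This is the package's test bed.  :func:`random_report` draws a
statistically plausible visual field — a hill-of-vision baseline with
eccentricity decay, seeded Gaussian-shaped defects scaled to a target
mean deviation in a chosen severity band, plus measurement noise —
and :func:`render` paints it as a report page in any of the three
layouts using the shipped glyph set.  :func:`degrade` applies seeded
resolution loss (downscale/upscale), blur and speckle to emulate the
low-quality exports on which extraction error rates rise.

The generator emulates the *geometry and statistics* of real reports
(test-point masks, value ranges, MD/PSD spreads, blind-spot icons); it
does not model SITA staircases or any normative database, so percentile
icons follow a fixed documented threshold map of the deviation values,
and device-font idiosyncrasies are out of scope.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import scipy.ndimage as ndi
from PIL import Image

from .data_model import (
    HvfMetadata,
    HvfReport,
    PercentileCell,
    PlotGrid,
    ValueCell,
)
from .glyphs import (
    CHAR_ADVANCE,
    CHAR_HEIGHT,
    CHAR_WIDTH,
    ICON_RASTERS,
    TRIANGLE_RASTER,
    TemplateSet,
    glyph_array,
    raster_to_array,
    scale_raster,
)
from .layout_registry import LayoutSpec, METADATA_FIELDS, region_pixels

# --- field patterns -------------------------------------------------------


@dataclass(frozen=True)
class FieldPattern:
    """Active and blind-spot grid cells of one test pattern, OD orientation."""

    pattern_id: str
    spacing_deg: float
    active: frozenset  # of (row, col)
    blind_spot: frozenset

    def __post_init__(self) -> None:
        if self.active & self.blind_spot:
            raise ValueError("active and blind-spot cells must be disjoint")
        for r, c in self.active | self.blind_spot:
            if not (0 <= r <= 9 and 0 <= c <= 9):
                raise ValueError(f"cell index out of range: {(r, c)}")

    def mirrored(self) -> "FieldPattern":
        """Column-mirrored mask (OS orientation)."""
        flip = lambda cells: frozenset((r, 9 - c) for r, c in cells)
        return FieldPattern(
            self.pattern_id, self.spacing_deg, flip(self.active),
            flip(self.blind_spot),
        )

    def for_laterality(self, laterality: str) -> "FieldPattern":
        return self if laterality == "OD" else self.mirrored()


def load_patterns() -> dict[str, FieldPattern]:
    doc = json.loads((resources.files("hvfkit.config") / "patterns.json").read_text())
    return {
        pid: FieldPattern(
            pattern_id=pid,
            spacing_deg=spec["spacing_deg"],
            active=frozenset(map(tuple, spec["active"])),
            blind_spot=frozenset(map(tuple, spec["blind_spot"])),
        )
        for pid, spec in doc.items()
    }


def get_pattern(pattern_id: str) -> FieldPattern:
    return load_patterns()[pattern_id]


# --- noise ----------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded degradation: downscale/upscale, Gaussian blur, speckle."""

    level: str = "CLEAN"  # CLEAN | L1 | L2
    downscale_factor: float = 1.0
    blur_radius: float = 0.0
    speckle_density: float = 0.0
    seed: int = 0

    @classmethod
    def preset(cls, level: str, seed: int = 0) -> "NoiseSpec":
        if level == "CLEAN":
            return cls("CLEAN", 1.0, 0.0, 0.0, seed)
        if level == "L1":
            return cls("L1", 0.95, 0.3, 3e-4, seed)
        if level == "L2":
            return cls("L2", 0.90, 0.5, 1e-3, seed)
        raise ValueError(f"unknown noise level {level!r}")


def degrade(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply the degradation chain; CLEAN is the identity. Deterministic."""
    if spec.level == "CLEAN":
        return image.copy()
    out = image
    if spec.downscale_factor < 1.0:
        h, w = out.shape
        small = Image.fromarray(out).resize(
            (max(1, int(w * spec.downscale_factor)),
             max(1, int(h * spec.downscale_factor))),
            Image.BILINEAR,
        )
        out = np.asarray(small.resize((w, h), Image.BILINEAR))
    if spec.blur_radius > 0:
        out = ndi.gaussian_filter(out.astype(np.float32), spec.blur_radius)
        out = np.clip(out, 0, 255).astype(np.uint8)
    if spec.speckle_density > 0:
        rng = np.random.default_rng(spec.seed)
        mask = rng.random(out.shape) < spec.speckle_density
        out = out.copy()
        out[mask] = np.where(rng.random(mask.sum()) < 0.5, 0, 255)
    return out


# --- ground-truth report generation ---------------------------------------

SEVERITY_MD_BANDS = {  # target-MD sampling bands, dB
    "MILD": (-5.5, -1.0),
    "MODERATE": (-11.5, -6.5),
    "SEVERE": (-19.0, -12.5),
}

# Deviation-to-percentile stand-in map (documented; real maps are
# proprietary normative data).  Applied to TD for the TD percentile plot
# and to PD for the PD percentile plot.
PERC_THRESHOLDS = ((-12, "P05"), (-8, "P1"), (-6, "P2"), (-4, "P5"))

_SURNAMES = [
    "SMITH", "GARCIA", "CHEN", "JOHNSON", "PATEL", "NGUYEN", "KIM",
    "HERNANDEZ", "OKAFOR", "MUELLER", "ROSSI", "TANAKA", "IVANOV",
    "DUBOIS", "ALI", "COHEN",
]
_GIVEN = [
    "JOHN", "MARIA", "WEI", "AISHA", "CARLOS", "YUKI", "ANNA", "OMAR",
    "LENA", "RAJ", "SOFIA", "DAVID", "MEI", "PAUL", "NIA", "IGOR",
]


def _percentile_kind(dev: int) -> str:
    for thr, kind in PERC_THRESHOLDS:
        if dev < thr:
            return kind
    return "NORMAL"


def random_report(
    seed: int,
    pattern: FieldPattern | str = "24-2",
    laterality: str = "OD",
    severity: str = "MILD",
    include_pd: bool = True,
) -> HvfReport:
    """Deterministic seeded ground-truth report.

    Raw sensitivities follow a hill-of-vision baseline (33 dB at
    fixation, −0.7 dB per 6° of eccentricity) minus a seeded defect
    field (1–3 Gaussian depressions, plus diffuse loss for SEVERE)
    rescaled so the mean total deviation lands on a target drawn inside
    the severity's MD band, plus N(0,1) test-retest noise.  Raw values
    below 0 dB print as "<0"; values are capped at 40 dB.
    """
    if isinstance(pattern, str):
        pattern = get_pattern(pattern)
    if severity not in SEVERITY_MD_BANDS:
        raise ValueError(f"unknown severity {severity!r}")
    pattern = pattern.for_laterality(laterality)
    rng = np.random.default_rng(seed)

    rows, cols = np.mgrid[0:10, 0:10]
    ecc_deg = pattern.spacing_deg * np.hypot(rows - 4.5, cols - 4.5)
    baseline = 33.0 - 0.7 * (ecc_deg / 6.0)

    active = sorted(pattern.active)
    amask = np.zeros((10, 10), bool)
    amask[tuple(np.array(active).T)] = True

    # seeded defect field: 1-3 Gaussian depressions (+ diffuse loss when severe)
    defect = np.zeros((10, 10))
    n_scot = int(rng.integers(1, 4))
    depth_hi = {"MILD": 8.0, "MODERATE": 18.0, "SEVERE": 35.0}[severity]
    for _ in range(n_scot):
        cr, cc = active[int(rng.integers(len(active)))]
        depth = rng.uniform(2.0, depth_hi)
        sigma = rng.uniform(1.0, 2.5)
        defect += depth * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2)
                                 / (2 * sigma**2))
    if severity == "SEVERE":
        defect += rng.uniform(5.0, 15.0)

    md_target = rng.uniform(*SEVERITY_MD_BANDS[severity])
    noise = rng.normal(0.0, 1.0, (10, 10))
    mean_defect = defect[amask].mean()
    k = (noise[amask].mean() - md_target) / max(mean_defect, 1e-9)
    td_real = noise - k * defect

    raw_grid = PlotGrid.empty("RAW")
    td_grid = PlotGrid.empty("TD_VALUE")
    pd_grid = PlotGrid.empty("PD_VALUE")
    tdp_grid = PlotGrid.empty("TD_PERC")
    pdp_grid = PlotGrid.empty("PD_PERC")

    td_int = {}
    for r, c in active:
        td_int[(r, c)] = int(np.clip(round(td_real[r, c]), -40, 10))
    gh = int(np.percentile(sorted(td_int.values()), 85, method="nearest"))

    for r, c in active:
        td = td_int[(r, c)]
        rawv = int(round(baseline[r, c])) + td
        if rawv < 0:
            raw_grid = raw_grid.with_cell(r, c, ValueCell("BELOW_THRESHOLD"))
        else:
            raw_grid = raw_grid.with_cell(r, c, ValueCell("NUMBER", min(rawv, 40)))
        td_grid = td_grid.with_cell(r, c, ValueCell("NUMBER", td))
        tdp_grid = tdp_grid.with_cell(r, c, PercentileCell(_percentile_kind(td)))
        if include_pd:
            pdv = int(np.clip(td - gh, -40, 50))
            pd_grid = pd_grid.with_cell(r, c, ValueCell("NUMBER", pdv))
            pdp_grid = pdp_grid.with_cell(r, c, PercentileCell(_percentile_kind(pdv)))
    for r, c in sorted(pattern.blind_spot):
        raw_grid = raw_grid.with_cell(r, c, ValueCell("BLIND_SPOT"))

    md = round(float(np.mean(list(td_int.values()))), 2)
    psd = round(float(np.std(list(td_int.values()))), 2)

    dob = _dt.date(int(rng.integers(1930, 1991)), int(rng.integers(1, 13)),
                   int(rng.integers(1, 29)))
    test_date = _dt.date(int(rng.integers(2014, 2021)), int(rng.integers(1, 13)),
                         int(rng.integers(1, 29)))
    dur = int(rng.integers(180, 600))
    sph = rng.integers(-24, 25) * 0.25
    cyl = rng.integers(0, 13) * 0.25
    axis = int(rng.integers(0, 181))
    fov = None
    if severity != "SEVERE" or rng.random() < 0.5:
        fov = float(int(np.clip(33 + md / 2 + rng.normal(0, 1.5), 5, 40)))

    metadata = HvfMetadata(
        name=f"{_SURNAMES[int(rng.integers(len(_SURNAMES)))]}, "
             f"{_GIVEN[int(rng.integers(len(_GIVEN)))]}",
        patient_id=str(int(rng.integers(10_000_000, 100_000_000))),
        date_of_birth=dob,
        test_date=test_date,
        laterality=laterality,
        foveal_sensitivity=fov,
        false_positive_rate=f"{int(rng.integers(0, 10))}%",
        false_negative_rate=f"{int(rng.integers(0, 12))}%",
        fixation_loss=f"{int(rng.integers(0, 5))}/{int(rng.integers(10, 21))}",
        test_duration=f"{dur // 60:02d}:{dur % 60:02d}",
        field_size=pattern.pattern_id,
        strategy=("SITA-Standard", "SITA-Fast", "SITA-Faster")[int(rng.integers(3))],
        pupil_diameter=round(float(rng.uniform(2.5, 6.5)), 1),
        refraction=f"{sph:+.2f}DS {cyl:+.2f}DC X {axis}",
        mean_deviation=md,
        pattern_standard_deviation=psd,
        vfi=int(np.clip(round(100 + 2.2 * md), 0, 100)),
    )
    return HvfReport(
        metadata=metadata,
        raw=raw_grid,
        td_value=td_grid,
        pd_value=pd_grid,
        td_perc=tdp_grid,
        pd_perc=pdp_grid,
        source_kind="SYNTHETIC",
        source=f"seed={seed}",
    )


# --- rendering ------------------------------------------------------------

_FIELD_DISPLAY_LABEL = None  # loaded lazily from the anchor config


def _labels() -> dict[str, str]:
    global _FIELD_DISPLAY_LABEL
    if _FIELD_DISPLAY_LABEL is None:
        doc = json.loads(
            (resources.files("hvfkit.config") / "anchors.json").read_text()
        )
        _FIELD_DISPLAY_LABEL = {fid: doc[fid]["labels"][0] for fid in doc}
    return _FIELD_DISPLAY_LABEL


def display_text(field_id: str, value) -> str:
    """Printed form of a canonical metadata value (as on a report)."""
    if value is None:
        return ""
    if isinstance(value, _dt.date):
        return f"{value.month:02d}-{value.day:02d}-{value.year}"
    if field_id in ("foveal_sensitivity", "mean_deviation",
                    "pattern_standard_deviation"):
        return f"{value:g} DB"
    if field_id == "pupil_diameter":
        return f"{value:g} MM"
    if field_id == "strategy":
        return value.upper().replace("-", " ")
    if field_id == "vfi":
        return f"{value}%"
    return str(value)


def draw_text(canvas: np.ndarray, x: int, y: int, text: str, scale: int) -> None:
    """Stamp monospaced text, top-left at (x, y). Ink = 0."""
    h, w = canvas.shape
    cx = x
    for ch in text.upper():
        if ch != " ":
            g = glyph_array(ch, scale)
            gh, gw = g.shape
            if 0 <= y and y + gh <= h and 0 <= cx and cx + gw <= w:
                region = canvas[y:y + gh, cx:cx + gw]
                region[g] = 0
        cx += CHAR_ADVANCE * scale


def text_width(text: str, scale: int) -> int:
    if not text:
        return 0
    return (CHAR_ADVANCE * len(text) - (CHAR_ADVANCE - CHAR_WIDTH)) * scale


def _stamp(canvas: np.ndarray, x: int, y: int, raster: np.ndarray) -> None:
    h, w = canvas.shape
    gh, gw = raster.shape
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + gw, w), min(y + gh, h)
    if x1 <= x0 or y1 <= y0:
        return
    sub = raster[y0 - y:y1 - y, x0 - x:x1 - x]
    region = canvas[y0:y1, x0:x1]
    region[sub] = 0


_TOKEN_GLYPH = {**{str(d): str(d) for d in range(10)}, "-": "MINUS", "<": "LT"}


def _axis_thickness(scale: int) -> int:
    return scale


def _plot_box(layout: LayoutSpec, plot_id: str) -> tuple[int, int, int, int, int]:
    """Rendered plot square inside the search window: (x0, y0, side, cell, t)."""
    W, H = layout.canonical_width, layout.canonical_height
    wx0, wy0, wx1, wy1 = region_pixels(layout, plot_id, W, H)
    cell = int(min(wx1 - wx0, wy1 - wy0) * 0.94) // 10
    side = cell * 10
    x0 = wx0 + (wx1 - wx0 - side) // 2
    y0 = wy0 + (wy1 - wy0 - side) // 2
    return x0, y0, side, cell, _axis_thickness(layout.glyph_scale)


def _cell_origin(x0: int, y0: int, cell: int, r: int, c: int,
                 content_w: int, content_h: int, t: int) -> tuple[int, int]:
    """Top-left for content centered in cell (r, c), nudged away from the
    central axes so the axis band never clips cell content."""
    gutter = t + 2
    cx = x0 + c * cell + (cell - content_w) // 2
    cy = y0 + r * cell + (cell - content_h) // 2
    if c == 4:
        cx = min(cx, x0 + 5 * cell - gutter - content_w)
    elif c == 5:
        cx = max(cx, x0 + 5 * cell + gutter)
    if r == 4:
        cy = min(cy, y0 + 5 * cell - gutter - content_h)
    elif r == 5:
        cy = max(cy, y0 + 5 * cell + gutter)
    return cx, cy


def render(
    report: HvfReport,
    layout: LayoutSpec,
    templates: TemplateSet | None = None,
) -> np.ndarray:
    """Paint a report page at the layout's canonical size (uint8, 255=paper).

    Deterministic: rendering the same report twice is byte-identical.
    ``templates`` may substitute alternate glyph artwork for the plots;
    the metadata font is always the shipped one.
    """
    scale = layout.glyph_scale
    W, H = layout.canonical_width, layout.canonical_height
    canvas = np.full((H, W), 255, dtype=np.uint8)

    labels = _labels()
    for fid in METADATA_FIELDS:
        x0, y0, _, _ = region_pixels(layout, fid, W, H)
        text = display_text(fid, report.metadata.get(fid))
        line = f"{labels[fid]}: {text}" if text else f"{labels[fid]}:"
        draw_text(canvas, x0 + 2 * scale, y0 + 2 * scale, line, scale)

    tri = (templates.glyphs["TRIANGLE"] if templates is not None
           else scale_raster(raster_to_array(TRIANGLE_RASTER), scale))

    for pid, grid in report.grids().items():
        x0, y0, side, cell, t = _plot_box(layout, pid)
        # axes crossing at the plot centre
        xc, yc = x0 + side // 2, y0 + side // 2
        canvas[y0:y0 + side, xc - t // 2: xc - t // 2 + t] = 0
        canvas[yc - t // 2: yc - t // 2 + t, x0:x0 + side] = 0
        for r in range(10):
            for c in range(10):
                cellobj = grid.cells[r][c]
                if cellobj.is_empty:
                    continue
                if cellobj.kind == "BLIND_SPOT":
                    gx, gy = _cell_origin(x0, y0, cell, r, c,
                                          tri.shape[1], tri.shape[0], t)
                    _stamp(canvas, gx, gy, tri)
                elif pid in ("TD_PERC", "PD_PERC"):
                    icon = (templates.icons[cellobj.kind] if templates is not None
                            else scale_raster(
                                raster_to_array(ICON_RASTERS[cellobj.kind]), scale))
                    gx, gy = _cell_origin(x0, y0, cell, r, c,
                                          icon.shape[1], icon.shape[0], t)
                    _stamp(canvas, gx, gy, icon)
                else:
                    token = cellobj.token()
                    if templates is None:
                        tw, th = text_width(token, scale), CHAR_HEIGHT * scale
                        gx, gy = _cell_origin(x0, y0, cell, r, c, tw, th, t)
                        draw_text(canvas, gx, gy, token, scale)
                    else:
                        rasters = [templates.glyphs[_TOKEN_GLYPH[ch]]
                                   for ch in token]
                        tw = (sum(g.shape[1] for g in rasters)
                              + scale * (len(rasters) - 1))
                        th = max(g.shape[0] for g in rasters)
                        gx, gy = _cell_origin(x0, y0, cell, r, c, tw, th, t)
                        for g in rasters:
                            _stamp(canvas, gx, gy + (th - g.shape[0]) // 2, g)
                            gx += g.shape[1] + scale
    return canvas


def save_png(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path, format="PNG")


def load_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))
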