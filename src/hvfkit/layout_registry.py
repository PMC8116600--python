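"""Report layout identification and region geometry.

Humphrey single-field-analysis reports come in three raster layouts:

* V1 — 650 x 938 px (HFA2, low resolution)
* V2 — 2400 x 3180 px (HFA2, high resolution)
* V3 — 3726 x 5262 px (HFA3, high resolution)

A :class:`LayoutSpec` records the canonical page size, the nominal glyph
scale, and a fractional bounding box for each of the 22 elements this
package addresses: the 17 metadata fields plus search windows for the
five perimetry plots.  Region maps are shipped as human-editable JSON
(``config/layout_v?.json``) because the coordinates are calibration
data, not algorithm: users with differently framed exports can point the
CLI at their own file.

Coordinate convention: origin top-left, x rightward, y downward,
half-open pixel boxes ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from math import ceil, floor
from pathlib import Path

METADATA_FIELDS = (
    "name", "patient_id", "date_of_birth", "test_date", "laterality",
    "foveal_sensitivity", "false_positive_rate", "false_negative_rate",
    "fixation_loss", "test_duration", "field_size", "strategy",
    "pupil_diameter", "refraction", "mean_deviation",
    "pattern_standard_deviation", "vfi",
)

PLOT_IDS = ("RAW", "TD_VALUE", "PD_VALUE", "TD_PERC", "PD_PERC")

ELEMENT_IDS = METADATA_FIELDS + PLOT_IDS

CANONICAL_DIMS = {"V1": (650, 938), "V2": (2400, 3180), "V3": (3726, 5262)}

#: relative tolerance on each axis when matching page dimensions
DIM_RTOL = 0.10
#: relative tolerance on the aspect ratio
ASPECT_RTOL = 0.05


class UnsupportedLayout(ValueError):
    """Raised when page dimensions match no registered layout."""

    def __init__(self, width: int, height: int):
        self.width, self.height = width, height
        super().__init__(
            f"no registered report layout matches {width}x{height} px"
        )


@dataclass(frozen=True)
class LayoutSpec:
    version: str
    canonical_width: int
    canonical_height: int
    glyph_scale: int
    regions: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        missing = [e for e in ELEMENT_IDS if e not in self.regions]
        if missing:
            raise ValueError(f"layout {self.version}: missing regions {missing}")
        for eid, (x0, y0, x1, y1) in self.regions.items():
            if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
                raise ValueError(
                    f"layout {self.version}: malformed region {eid}: "
                    f"{(x0, y0, x1, y1)}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "LayoutSpec":
        doc = json.loads(Path(path).read_text())
        return cls(
            version=doc["version"],
            canonical_width=doc["canonical_width"],
            canonical_height=doc["canonical_height"],
            glyph_scale=doc["glyph_scale"],
            regions={k: tuple(v) for k, v in doc["regions"].items()},
        )


def _builtin(version: str) -> LayoutSpec:
    ref = resources.files("hvfkit.config") / f"layout_{version.lower()}.json"
    doc = json.loads(ref.read_text())
    return LayoutSpec(
        version=doc["version"],
        canonical_width=doc["canonical_width"],
        canonical_height=doc["canonical_height"],
        glyph_scale=doc["glyph_scale"],
        regions={k: tuple(v) for k, v in doc["regions"].items()},
    )


def builtin_layouts() -> dict[str, LayoutSpec]:
    """The three shipped layouts, keyed by version."""
    return {v: _builtin(v) for v in CANONICAL_DIMS}


def get_layout(version: str) -> LayoutSpec:
    if version not in CANONICAL_DIMS:
        raise ValueError(f"unknown layout version {version!r}")
    return _builtin(version)


def detect_layout(
    width: int, height: int, candidates: dict[str, LayoutSpec] | None = None
) -> LayoutSpec:
    """Pick the layout whose canonical page size matches ``(width, height)``.

    Both axes must agree within ±10% and the aspect ratio within ±5%,
    tolerating mildly rescaled exports while rejecting foreign documents.
    """
    if width <= 0 or height <= 0:
        raise ValueError("page dimensions must be positive")
    candidates = candidates if candidates is not None else builtin_layouts()
    best, best_err = None, None
    for spec in candidates.values():
        cw, ch = spec.canonical_width, spec.canonical_height
        ew, eh = abs(width - cw) / cw, abs(height - ch) / ch
        ea = abs((width / height) - (cw / ch)) / (cw / ch)
        if ew <= DIM_RTOL and eh <= DIM_RTOL and ea <= ASPECT_RTOL:
            err = ew + eh
            if best_err is None or err < best_err:
                best, best_err = spec, err
    if best is None:
        raise UnsupportedLayout(width, height)
    return best


def region_pixels(
    layout: LayoutSpec, element_id: str, width: int, height: int
) -> tuple[int, int, int, int]:
    """Scale a fractional region to integer pixels, rounded outward."""
    if element_id not in layout.regions:
        raise KeyError(f"unknown element_id {element_id!r}")
    x0, y0, x1, y1 = layout.regions[element_id]
    px0, py0 = floor(x0 * width), floor(y0 * height)
    px1, py1 = ceil(x1 * width), ceil(y1 * height)
    px1, py1 = min(px1, width), min(py1, height)
    if px1 <= px0:
        px1 = px0 + 1
    if py1 <= py0:
        py1 = py0 + 1
    return px0, py0, px1, py1
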