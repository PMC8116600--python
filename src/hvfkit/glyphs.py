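"""Canonical glyph and icon artwork.

The report renderer and the template-matching recognizer share one
monospaced 5x7 dot-matrix font, scaled by an integer factor per report
layout (`LayoutSpec.glyph_scale`).  Shipping the font with the package
keeps the whole pipeline testable without any device fonts; users who
want to match real HFA prints can drop replacement templates into a
directory with the same structure (see `TemplateSet.from_dir`).

Glyphs are stored as tuples of row strings, ``#`` = ink.  All value-plot
tokens are built from digits, MINUS, LT ("<") and the open blind-spot
TRIANGLE; percentile plots use five icon rasters whose *internal texture*
(not just size) distinguishes them, so that bounding-box-normalized
template matching can tell a small normal dot-pair from a solid
worst-percentile box.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# --- 5x7 dot matrix font -------------------------------------------------

FONT_RASTERS: dict[str, tuple[str, ...]] = {
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "B": ("####.", "#...#", "#...#", "####.", "#...#", "#...#", "####."),
    "C": (".###.", "#...#", "#....", "#....", "#....", "#...#", ".###."),
    "D": ("####.", "#...#", "#...#", "#...#", "#...#", "#...#", "####."),
    "E": ("#####", "#....", "#....", "####.", "#....", "#....", "#####"),
    "F": ("#####", "#....", "#....", "####.", "#....", "#....", "#...."),
    "G": (".###.", "#...#", "#....", "#.###", "#...#", "#...#", ".####"),
    "H": ("#...#", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "I": (".###.", "..#..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "J": ("..###", "...#.", "...#.", "...#.", "...#.", "#..#.", ".##.."),
    "K": ("#...#", "#..#.", "#.#..", "##...", "#.#..", "#..#.", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#....", "#....", "#####"),
    "M": ("#...#", "##.##", "#.#.#", "#.#.#", "#...#", "#...#", "#...#"),
    "N": ("#...#", "##..#", "#.#.#", "#..##", "#...#", "#...#", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "P": ("####.", "#...#", "#...#", "####.", "#....", "#....", "#...."),
    "Q": (".###.", "#...#", "#...#", "#...#", "#.#.#", "#..#.", ".##.#"),
    "R": ("####.", "#...#", "#...#", "####.", "#.#..", "#..#.", "#...#"),
    "S": (".####", "#....", "#....", ".###.", "....#", "....#", "####."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "V": ("#...#", "#...#", "#...#", "#...#", "#...#", ".#.#.", "..#.."),
    "W": ("#...#", "#...#", "#...#", "#.#.#", "#.#.#", "##.##", "#...#"),
    "X": ("#...#", "#...#", ".#.#.", "..#..", ".#.#.", "#...#", "#...#"),
    "Y": ("#...#", "#...#", ".#.#.", "..#..", "..#..", "..#..", "..#.."),
    "Z": ("#####", "....#", "...#.", "..#..", ".#...", "#....", "#####"),
    "0": (".###.", "#...#", "#..##", "#.#.#", "##..#", "#...#", ".###."),
    "1": ("..#..", ".##..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "2": (".###.", "#...#", "....#", "...#.", "..#..", ".#...", "#####"),
    "3": ("#####", "...#.", "..#..", "...#.", "....#", "#...#", ".###."),
    "4": ("...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."),
    "5": ("#####", "#....", "####.", "....#", "....#", "#...#", ".###."),
    "6": ("..##.", ".#...", "#....", "####.", "#...#", "#...#", ".###."),
    "7": ("#####", "....#", "...#.", "..#..", ".#...", ".#...", ".#..."),
    "8": (".###.", "#...#", "#...#", ".###.", "#...#", "#...#", ".###."),
    "9": (".###.", "#...#", "#...#", ".####", "....#", "...#.", ".##.."),
    "-": (".....", ".....", ".....", "#####", ".....", ".....", "....."),
    "+": (".....", "..#..", "..#..", "#####", "..#..", "..#..", "....."),
    ":": (".....", "..#..", "..#..", ".....", "..#..", "..#..", "....."),
    "/": ("....#", "....#", "...#.", "..#..", ".#...", "#....", "#...."),
    ".": (".....", ".....", ".....", ".....", ".....", ".##..", ".##.."),
    ",": (".....", ".....", ".....", ".....", "..##.", "..#..", ".#..."),
    "(": ("...#.", "..#..", ".#...", ".#...", ".#...", "..#..", "...#."),
    ")": (".#...", "..#..", "...#.", "...#.", "...#.", "..#..", ".#..."),
    "<": ("...#.", "..#..", ".#...", "#....", ".#...", "..#..", "...#."),
    ">": (".#...", "..#..", "...#.", "....#", "...#.", "..#..", ".#..."),
    "%": ("##..#", "##..#", "...#.", "..#..", ".#...", "#..##", "#..##"),
}

#: glyph cell advance in units of the base (unscaled) font.
CHAR_WIDTH = 5
CHAR_HEIGHT = 7
CHAR_ADVANCE = 6  # 5 ink columns + 1 guaranteed blank column

# Open triangle marking the physiologic blind spot on raw sensitivity plots.
TRIANGLE_RASTER: tuple[str, ...] = (
    "....#....",
    "...#.#...",
    "..#...#..",
    ".#.....#.",
    "#.......#",
    "#########",
)

# Percentile-icon artwork (9x9 base).  Semantics, from least to most
# abnormal: NORMAL (within normal limits), P5 (<5%), P2 (<2%), P1 (<1%),
# P05 (<0.5%, solid).  Textures are pairwise distinct under normalized
# cross-correlation even after bounding-box size normalization.
ICON_RASTERS: dict[str, tuple[str, ...]] = {
    "NORMAL": (
        ".........",
        ".........",
        ".........",
        ".........",
        ".##...##.",
        ".##...##.",
        ".........",
        ".........",
        ".........",
    ),
    "P5": (
        "##.....##",
        "##.....##",
        ".........",
        ".........",
        "...###...",
        "...###...",
        ".........",
        "##.....##",
        "##.....##",
    ),
    "P2": (
        "#.....#..",
        ".#.....#.",
        "..#.....#",
        "#..#.....",
        ".#..#....",
        "..#..#...",
        "...#..#..",
        "....#..#.",
        ".....#..#",
    ),
    "P1": (
        "#.#.#.#.#",
        ".#.#.#.#.",
        "#.#.#.#.#",
        ".#.#.#.#.",
        "#.#.#.#.#",
        ".#.#.#.#.",
        "#.#.#.#.#",
        ".#.#.#.#.",
        "#.#.#.#.#",
    ),
    "P05": (
        "#########",
        "#########",
        "#########",
        "#########",
        "#########",
        "#########",
        "#########",
        "#########",
        "#########",
    ),
}

# Alternate digit artwork (different stroke choices: open-loop 0, wide-base
# 1, flat-top 3, closed 4, ...).  Rendering with this set while matching
# against the canonical templates exercises cross-font tolerance the way a
# device font would, without shipping vendor artwork.
ALT_DIGIT_RASTERS: dict[str, tuple[str, ...]] = {
    "0": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "1": ("..#..", "###..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "2": (".###.", "#...#", "....#", "..##.", ".#...", "#....", "#####"),
    "3": ("#####", "...#.", "..#..", "...##", "....#", "#...#", ".###."),
    "4": ("#..#.", "#..#.", "#..#.", "#####", "...#.", "...#.", "...#."),
    "5": ("#####", "#....", "####.", "....#", "....#", "....#", "####."),
    "6": ("...#.", "..#..", ".#...", "####.", "#...#", "#...#", ".###."),
    "7": ("#####", "....#", "...#.", "..#..", "..#..", ".#...", ".#..."),
    "8": (".###.", "#...#", "#..##", ".###.", "##..#", "#...#", ".###."),
    "9": (".###.", "#...#", "#...#", ".####", "....#", "..#..", ".#..."),
}

VALUE_GLYPH_IDS = [str(d) for d in range(10)] + ["MINUS", "LT", "TRIANGLE"]
ICON_IDS = ["NORMAL", "P5", "P2", "P1", "P05"]

_GLYPH_CHAR = {"MINUS": "-", "LT": "<"}


def raster_to_array(rows: tuple[str, ...]) -> np.ndarray:
    """Convert a row-string raster to a binary (bool) array, ink=True."""
    return np.array([[c == "#" for c in row] for row in rows], dtype=bool)


def scale_raster(a: np.ndarray, factor: int) -> np.ndarray:
    """Integer nearest-neighbour upscale (block replication)."""
    if factor < 1:
        raise ValueError("scale factor must be >= 1")
    return np.kron(a, np.ones((factor, factor), dtype=a.dtype))


def glyph_array(char: str, scale: int = 1) -> np.ndarray:
    """Binary raster of one font character at an integer scale."""
    return scale_raster(raster_to_array(FONT_RASTERS[char.upper()]), scale)


@dataclass(frozen=True)
class TemplateSet:
    """Reference rasters used by the template-matching recognizer.

    ``glyphs`` maps "0".."9", "MINUS", "LT", "TRIANGLE" to binary rasters;
    ``icons`` maps the five percentile classes.  ``version`` records which
    layout scale the rasters were produced at (informational: matching is
    size-normalized).
    """

    version: str
    glyphs: dict[str, np.ndarray]
    icons: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [g for g in VALUE_GLYPH_IDS if g not in self.glyphs]
        missing += [i for i in ICON_IDS if i not in self.icons]
        if missing:
            raise ValueError(f"template set incomplete, missing {missing}")
        for name, arr in {**self.glyphs, **self.icons}.items():
            if arr.size == 0 or not arr.any():
                raise ValueError(f"template {name!r} is empty")

    @classmethod
    def canonical(cls, version: str = "V1", scale: int = 1) -> "TemplateSet":
        glyphs = {}
        for gid in VALUE_GLYPH_IDS:
            if gid == "TRIANGLE":
                base = raster_to_array(TRIANGLE_RASTER)
            else:
                base = raster_to_array(FONT_RASTERS[_GLYPH_CHAR.get(gid, gid)])
            glyphs[gid] = scale_raster(base, scale)
        icons = {
            iid: scale_raster(raster_to_array(ICON_RASTERS[iid]), scale)
            for iid in ICON_IDS
        }
        return cls(version=version, glyphs=glyphs, icons=icons)

    @classmethod
    def alternate(cls, version: str = "ALT", scale: int = 1) -> "TemplateSet":
        """Canonical set with the alternate digit artwork substituted."""
        base = cls.canonical(version, scale)
        glyphs = dict(base.glyphs)
        for d, rows in ALT_DIGIT_RASTERS.items():
            glyphs[d] = scale_raster(raster_to_array(rows), scale)
        return cls(version=version, glyphs=glyphs, icons=dict(base.icons))

    @classmethod
    def from_dir(cls, path: str | Path, version: str = "custom") -> "TemplateSet":
        """Load templates from ``<path>/glyphs/<id>.png`` and
        ``<path>/icons/<id>.png`` (any raster Pillow reads; ink = dark)."""
        from PIL import Image

        path = Path(path)
        def load(p: Path) -> np.ndarray:
            return np.asarray(Image.open(p).convert("L")) < 128

        glyphs = {g: load(path / "glyphs" / f"{g}.png") for g in VALUE_GLYPH_IDS}
        icons = {i: load(path / "icons" / f"{i}.png") for i in ICON_IDS}
        return cls(version=version, glyphs=glyphs, icons=icons)
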