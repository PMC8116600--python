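"""Plot location and 10x10 grid partitioning.

Each perimetry plot is found inside its layout search window by its
axes: the only full-length dark vertical and horizontal strokes in the
window.  Detection uses per-column / per-row ink counts (tolerant of
small speckle gaps, unlike a strict run-length test) with a 60%-of-
extent threshold.  The axes' extents span the plot square; the grid is
registered assuming the axes cross at the plot centre, five cells to
each side, which matches HFA plot symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .layout_registry import LayoutSpec, PLOT_IDS, region_pixels


class PlotNotFound(ValueError):
    def __init__(self, plot_id: str):
        self.plot_id = plot_id
        super().__init__(f"no plot axes found in the {plot_id} search window")


@dataclass(frozen=True)
class PlotGeometry:
    plot_box: tuple[int, int, int, int]  # (x0, y0, x1, y1), full-image px
    axis_cross: tuple[int, int]  # (x, y)
    cell_width: float
    cell_height: float
    axis_thickness: int

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.plot_box
        ax, ay = self.axis_cross
        if not (x0 <= ax <= x1 and y0 <= ay <= y1):
            raise ValueError("axis crossing outside plot box")
        if abs(10 * self.cell_width - (x1 - x0)) > 1 or \
           abs(10 * self.cell_height - (y1 - y0)) > 1:
            raise ValueError("cells do not tile the plot box")


def binarize(image: np.ndarray) -> np.ndarray:
    """Page image (uint8 grayscale or bool) to ink mask (True = dark)."""
    if image.dtype == bool:
        return image
    img = np.asarray(image)
    if img.min() == img.max():  # blank page
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(img)
    # Otsu on a nearly blank page can split paper texture; never accept a
    # threshold that calls more than half the page ink.
    mask = img <= thr
    if mask.mean() > 0.5:
        mask = img < 128
    return mask


def _axis_profile(ink: np.ndarray, axis: int) -> np.ndarray:
    return ink.sum(axis=axis)


def _longest_run(mask: np.ndarray, max_gap: int = 3) -> tuple[int, int] | None:
    """Longest True run in a 1-D mask, bridging gaps up to ``max_gap``.

    Keeps isolated speckle away from the axis extent: a stray ink pixel
    elsewhere on the line's row/column must not stretch the plot box.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]
    return max(runs, key=lambda r: r[1] - r[0])


def _find_axis(ink: np.ndarray, axis: int, min_frac: float = 0.6):
    """Locate the dominant full-length line perpendicular to ``axis``.

    Returns (centre index, thickness, extent_lo, extent_hi) or None.
    For axis=0 the profile is per-column (vertical line), axis=1 per-row.
    """
    counts = _axis_profile(ink, axis)
    extent = ink.shape[0] if axis == 0 else ink.shape[1]
    best = int(np.argmax(counts))
    if counts[best] < min_frac * extent:
        return None
    # contiguous band of comparable ink around the peak = line thickness
    lo = best
    while lo > 0 and counts[lo - 1] >= 0.8 * counts[best]:
        lo -= 1
    hi = best
    while hi < len(counts) - 1 and counts[hi + 1] >= 0.8 * counts[best]:
        hi += 1
    line = ink[:, lo:hi + 1] if axis == 0 else ink[lo:hi + 1, :]
    profile = line.any(axis=1) if axis == 0 else line.any(axis=0)
    span = _longest_run(profile, max_gap=3)
    if span is None:
        return None
    return (lo + hi) // 2, hi - lo + 1, span[0], span[1]


def locate_plot(image: np.ndarray, layout: LayoutSpec, plot_id: str) -> PlotGeometry:
    """Find one plot's geometry inside its layout search window."""
    if plot_id not in PLOT_IDS:
        raise KeyError(f"unknown plot_id {plot_id!r}")
    ink = binarize(image)
    H, W = ink.shape
    wx0, wy0, wx1, wy1 = region_pixels(layout, plot_id, W, H)
    window = ink[wy0:wy1, wx0:wx1]

    vert = _find_axis(window, axis=0)
    horiz = _find_axis(window, axis=1)
    if vert is None or horiz is None:
        raise PlotNotFound(plot_id)
    vx, vt, vy0, vy1 = vert  # vertical axis: x position, y extent
    hy, ht, hx0, hx1 = horiz  # horizontal axis: y position, x extent

    box = (wx0 + hx0, wy0 + vy0, wx0 + hx1, wy0 + vy1)
    cross = (wx0 + vx, wy0 + hy)
    return PlotGeometry(
        plot_box=box,
        axis_cross=cross,
        cell_width=(box[2] - box[0]) / 10.0,
        cell_height=(box[3] - box[1]) / 10.0,
        axis_thickness=max(vt, ht),
    )


def split_grid(image: np.ndarray, geom: PlotGeometry) -> list[np.ndarray]:
    """Cut the plot into 100 binary cell rasters, row-major.

    Cells tile the plot box exactly; pixels within one thickness of the
    central axes are masked to background so line ink (and its blur
    bleed) cannot contaminate the cell content.
    """
    if geom.cell_width < 4 or geom.cell_height < 4:
        raise ValueError(f"degenerate plot geometry: cells {geom.cell_width:.1f}"
                         f"x{geom.cell_height:.1f} px")
    ink = binarize(image)
    x0, y0, x1, y1 = geom.plot_box
    plot = ink[y0:y1, x0:x1].copy()
    ax, ay = geom.axis_cross[0] - x0, geom.axis_cross[1] - y0
    band = geom.axis_thickness
    plot[:, max(0, ax - band):ax + band + 1] = False
    plot[max(0, ay - band):ay + band + 1, :] = False

    xs = [round(c * geom.cell_width) for c in range(11)]
    ys = [round(r * geom.cell_height) for r in range(11)]
    xs[10], ys[10] = x1 - x0, y1 - y0
    return [
        plot[ys[r]:ys[r + 1], xs[c]:xs[c + 1]]
        for r in range(10)
        for c in range(10)
    ]
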