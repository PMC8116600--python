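# Methods

This note documents the models, conventions and numerical choices
behind `hvfkit`, in the order data flows through the package.

## Report model

An `HvfReport` is the complete structured content of one Humphrey
single-field-analysis report: 17 metadata fields, three 10×10 value
grids (raw sensitivity, total deviation, pattern deviation, integer
dB), and two 10×10 percentile-icon grids. Grid row 0 is the top of the
printed plot, column 0 the left, indexing row-major.

Cell states are deliberately richer than "a number or nothing":

* `"<0"` (stimulus not seen at maximal intensity) is a distinct
  `BELOW_THRESHOLD` state. Collapsing it to 0 or −1 would silently
  erase a clinically meaningful distinction, and `"<0"` vs `"0"` is a
  genuine extraction error class, so the two must compare unequal.
* The physiologic blind spot (≈15° temporal, on the horizontal
  midline) is a `BLIND_SPOT` state rendered as the open triangle icon.
* Percentile cells carry one of NORMAL / P5 / P2 / P1 / P05
  (< 5%, 2%, 1%, 0.5% of the normative distribution).

Field normalization (`normalize_field`) maps raw text to canonical
typed values: dates to ISO 8601 (inputs accept the `MM-DD-YYYY` and
`MM/DD/YYYY` dialects printed on reports), durations to zero-padded
`mm:ss` (with a seconds accessor), laterality/field-size/strategy to
closed enums, decibel quantities to floats with signs and units
handled. Unparseable input becomes the explicit ABSENT marker
(`None`) — never a guessed default. Fixation loss stays ratio text
(`"2/15"`) with parsed accessors: lossless is safer when the reference
representation is not fixed.

JSON serialization is versioned (`schema_version: "1.0"`) and
deterministic (fixed key order, so equal reports serialize
byte-identically). The tab-delimited export flattens each report to
`2 + 17 + 500` columns (provenance, metadata in the fixed field order,
then `<grid>_r<row>c<col>` row-major; empty cells blank).

## Layouts and calibration data

Three raster layouts are supported, identified purely by page size
(±10% per axis, aspect ratio within 5% — tolerant of rescaled exports,
rejecting foreign documents):

| version | page (px)   | glyph scale |
|---------|-------------|-------------|
| V1      | 650×938     | 1 (5×7 font) |
| V2      | 2400×3180   | 3           |
| V3      | 3726×5262   | 5           |

Every layout carries a fractional region map for 22 elements (17
metadata crops + 5 plot search windows), shipped as human-editable
JSON. Coordinates are calibration data, not algorithm: users with
differently framed exports can recalibrate without touching code. The
coordinate convention is origin top-left, x rightward, y downward,
half-open pixel boxes.

## OCR engine

No external OCR engine is used. Both metadata text and plot cells go
through one template-matching recognizer over a shipped monospaced 5×7
dot-matrix font (scaled per layout), which keeps the pipeline fully
deterministic and self-contained; replacement device-font templates can
be dropped in via `TemplateSet.from_dir`.

Similarity between two binary rasters is the normalized
cross-correlation after cropping each to its ink bounding box and
nearest-neighbour resizing both to their common (elementwise-max)
shape, mapped to [0, 1]; identical rasters score exactly 1. Candidate
scoring additionally multiplies by an aspect-consistency factor
`sqrt(min(r_a, r_b)/max(r_a, r_b))` of the two bounding-box aspect
ratios, because bounding-box normalization alone cannot tell a period
from a dash (both normalize to a solid block). Tie-breaks use a fixed
candidate order, so recognition is deterministic.

Metadata OCR segments a crop into line bands (row-projection runs) and
characters (column-projection runs); with the monospaced geometry,
intra-word bounding-box gaps stay below ~4.5× the glyph scale while
word spaces exceed ~7×, so 5.5× splits them cleanly. Each field's
line(s) are anchored by fuzzy label matching: normalized Levenshtein
similarity (`100·(1 − d/max(len))`, case-folded) against the anchor
table's label variants, threshold 85 — high enough to reject
cross-field captures, low enough to absorb single-character OCR slips
(one substitution in a 15-character label leaves similarity 93.3). The
value is then pulled out with the anchor's regular expression and
normalized. A field whose region yields no text is ABSENT, never
fabricated.

## Plot extraction

Within each search window the plot axes are the only full-length dark
strokes. Per-column/per-row ink counts locate them (peak ≥ 60% of the
window extent); the axis extent is the longest gap-tolerant ink run
(gaps ≤ 3 px bridged) rather than the raw ink span, so an isolated
speckle pixel in the axis row cannot stretch the plot box. The axes'
extents span the plot square; grid registration assumes the axes cross
at the plot centre, five cells to each side (HFA plot symmetry — a
documented calibration assumption). Cells tile the box exactly;
pixels within one detected line thickness of the axes are masked to
background so line ink and its blur bleed never contaminate cells.
Thin full-height/width strips surviving at a cell border are discarded
as axis residue before matching.

Value cells are segmented into 8-connected components; specks below
`max(4, 0.2%)` of the cell area are noise. A minus sign is recognized
*structurally* (width ≥ 2× height, fill > 60%) before any correlation:
a thin dash correlates poorly, and a dropped minus sign silently flips
a deviation value's sign. Components overlapping horizontally by > 70%
are merged (fragmented glyphs); conversely a component whose best
match scores below 0.85 and whose box is wider than 1.15× its height
is suspected of being two blur-merged glyphs and is split at its
weakest interior column when the halves match better than the whole.
Repeated MINUS components collapse to one sign (degradation snaps the
bar). Triangle ink — whole icon or the half-icon fragments that
intrude on neighbouring cells near the blind spot — is matched
explicitly (whole + half templates) and stripped before token
assembly; a cell that is all triangle is the blind spot. A token that
parses to nothing legal raises `UnreadableCell` (the pipeline degrades
it to a warning and an empty cell) rather than guessing.

Percentile cells are simpler: the union of the cell's ink is matched
whole against the five icon textures plus the triangle; argmax wins.
The icon artwork is designed so the *internal texture* (dot pair,
corner stipple, diagonal hatch, checkerboard, solid) separates classes
even after size normalization.

## DICOM ingest

OPV datasets map to the same structure through an editable public-tag
map (`config/opv_tags.json`). Per-point placement converts angular
coordinates to grid indices — `col = x/s + 4.5`, `row = 4.5 − y/s`,
spacing s = 6° (24-2/30-2) or 2° (10-2), x positive temporal for OD
and mirrored for OS — standard HFA chart geometry, adopted as a
documented convention. Three per-point conventions cover the
non-numeric states: `SEEN` + sensitivity for numbers, `NOT SEEN` +
sensitivity 0 for below-threshold, `NOT SEEN` without a sensitivity
value for blind-spot points (the OPV object has no per-point
blind-spot flag). The fixture writer emits minimal explicit-VR
little-endian datasets; round-trip is the identity on all mapped
fields. Vendor-private attributes are ignored — their semantics are
unverifiable without device files. Free-text refractions not following
the `{sph}DS {cyl}DC X {axis}` convention are not representable in the
refractive-parameters sequence and read back ABSENT.

## Synthetic reports

The generator defines the package's study conditions:

* **Test patterns.** 24-2 (54 points), 30-2 (76), 10-2 (68) on the
  standard 6°/2° lattices, stored as configuration. Two of the 54/76
  points coincide with the blind spot and are kept as a disjoint
  blind-spot set, so `|active|` is 52/74/68.
* **Sensitivities.** Hill of vision: 33 dB at fixation, −0.7 dB per 6°
  of eccentricity. Defects: 1–3 Gaussian-shaped depressions (depth up
  to 8/18/35 dB by severity, σ 1–2.5 cells; severe fields add 5–15 dB
  diffuse loss), linearly rescaled so the mean total deviation lands on
  a target drawn inside the severity band (MILD −5.5…−1, MODERATE
  −11.5…−6.5, SEVERE −19…−12.5 dB); N(0, 1) test–retest noise. Raw
  values below 0 print as `<0`; values cap at 40 dB.
* **Derived plots.** TD = raw − baseline (rounded); general height =
  85th percentile of TD; PD = TD − general height. The percentile map
  (TD/PD < −12 → P05, < −8 → P1, < −6 → P2, < −4 → P5, else NORMAL) is
  a fixed documented stand-in — real maps are proprietary normative
  data, and only internal consistency matters for round-trip testing.
  Reports that omit PD plots (as severely depressed real fields do)
  are produced via an explicit `include_pd=False` flag, since the
  device's trigger rule is not public.
* **Metadata** are plausible seeded values (names from a fixed list,
  MD/PSD computed from the generated grids, VFI ≈ 100 + 2.2·MD).
* **Degradation.** `degrade` applies downscale→upscale (bilinear),
  Gaussian blur, then seeded salt-and-pepper speckle. CLEAN is the
  identity. L1 (downscale 0.95, Gaussian σ 0.3 px, speckle 3×10⁻⁴)
  was calibrated once to reproduce the sub-1% per-point error
  regime characteristic of low-resolution extraction, with the
  digit-shape confusions (8↔0, 28↔20, merged `-40` tokens) that regime
  shows; L2 (0.90/0.5/10⁻³) is strictly harsher. The error rate is
  strongly non-monotonic in the downscale factor because of resampling
  phase against the 1-px strokes of the scale-1 font.

What passing tests show — and what they do not: the renderer and the
recognizer share one glyph set, so clean round-trip exactness proves
the geometry, segmentation, anchoring, normalization and serialization
plumbing end to end, and the degradation suite proves robustness to
resolution loss; neither proves accuracy against Zeiss device fonts or
scanner artefacts, which is a calibration (template/region) question,
not an algorithmic one.

## Validation statistics

Comparison is text-level. Metadata fields: exact equality → MATCH;
otherwise both sides are canonicalized (case fold, whitespace
collapse, date/number/unit normalization per field type) — equal
canonical forms → FORMAT_INCONSISTENCY, anything else → TRUE_ERROR.
The explicit rule list makes the classifier deterministic and
auditable. Plot points admit only MATCH or TRUE_ERROR and are
enumerated over non-empty *reference* cells (extra extracted ink
surfaces as pipeline warnings, not counted items).

Aggregates: error rate = 100·errors/items with the exact two-sided
Clopper–Pearson 95% interval (beta-quantile form; the test suite
verifies agreement to 1e-6 with direct bisection of the binomial tails
for all x ≤ n ≤ 200); per-report counts summarized as median and
median-inclusive (Tukey hinge) quartiles — the convention is fixed and
documented because several exist. Interval bounds are reported as
percentages rounded to one decimal.

## Problem sizes used by the test suite

Round-trip exactness runs 30 seeded reports per high-resolution layout
(V2, V3); low-resolution robustness runs 30 V1 pages at L1 (~5,900
value points); serialization identities run 50 seeded reports; the
statistics oracle covers all 20,301 (x, n) pairs with n ≤ 200. These
sizes keep the full suite around four minutes on one CPU while leaving
every assertion exact rather than sampled.

## Known limitations

* No deskew/perspective correction: inputs are digital exports, not
  photographs or scans.
* Single-field-analysis pages only; no progression-analysis layouts,
  no Full-Threshold glyph variants, no non-English locales.
* Shipped percentile icon artwork and glyph font are stand-ins with
  documented semantics, not reproductions of device artwork.
* The V1 layout at noise level L1 retains a ~0.8% per-point error rate
  (dominated by three-glyph negative tokens in 20-px cells); this is
  inherent to 5×7 glyphs under resampling, and mirrors the error
  profile low-resolution extraction shows in practice.
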