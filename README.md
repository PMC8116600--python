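# hvfkit

Structured data extraction, synthesis and validation for Humphrey visual
field (HVF) single-field-analysis reports.

Static automated perimetry is central to managing glaucoma and
neuro-ophthalmic disease, but the device output most clinics can
actually get at is a raster image of the printed report. Research that
needs thousands of fields — progression modelling, machine learning,
new global indices — needs those images converted back into numbers.
`hvfkit` does that conversion and, just as importantly, ships the
validation machinery to *measure* how well any such conversion works.

The package provides:

* **Extraction** — a report image (any of the three HFA raster layouts:
  650×938, 2400×3180, 3726×5262 px) is dispatched by page size, the 17
  metadata fields (name, ID, dates, laterality, reliability indices,
  test parameters, MD, PSD, VFI, …) are cropped per field, OCR'd by a
  custom template-matching engine and anchored to their labels by fuzzy
  (normalized Levenshtein) matching; the five plots — raw sensitivity,
  total-deviation (TD) and pattern-deviation (PD) value plots, TD/PD
  percentile plots — are located by their axes, aligned to a 10×10
  grid, and each cell is classified by normalized cross-correlation
  against glyph/icon templates into a number, `<0` (below threshold),
  a blind-spot triangle, a percentile icon, or empty.
* **OPV DICOM ingest** — ophthalmic visual field DICOM files are read
  into the same structure through an editable public-tag map; this is
  the reference pathway for validation.
* **Serialization** — lossless, versioned JSON round-trip and a
  tab-delimited export for spreadsheets.
* **Synthetic reports** — a seeded generator produces ground-truth
  fields (hill-of-vision baseline, Gaussian scotomata scaled to a
  target mean deviation in a chosen severity band) and renders them as
  pages in any layout, with controllable degradation (downscale, blur,
  speckle). The whole pipeline is therefore testable with zero patient
  data.
* **Validation statistics** — extraction vs reference comparison with a
  three-way taxonomy (exact match / format inconsistency / true error),
  aggregate error rates with exact two-sided Clopper–Pearson 95%
  confidence intervals, and median (Q1, Q3) per-report error counts.

The Clopper–Pearson interval for `x` errors in `n` items inverts the
binomial tails; in the beta-quantile form used here:

    low  = B(α/2;     x,     n−x+1)
    high = B(1−α/2;   x+1,   n−x)

with `low = 0` when `x = 0` and `high = 1` when `x = n`.

## Worked example

```python
import hvfkit as hk

# ground truth: a moderate 24-2 right-eye field, fully seeded
rep = hk.random_report(seed=7, pattern="24-2", laterality="OD",
                       severity="MODERATE")

# render it as a 2400x3180 page and extract it back
lay = hk.get_layout("V2")
img = hk.render(rep, lay)
out, warnings = hk.extract_report(img, lay)

md = out.metadata
print("MD:", md.mean_deviation, "PSD:", md.pattern_standard_deviation,
      "VFI:", md.vfi)
print("strategy:", md.strategy, "field:", md.field_size, "eye:", md.laterality)
print("raw row 4:", [c.token() for c in out.raw.cells[4]])

pairs = hk.compare_reports(out, rep)
print("metadata:", hk.summarize([pairs["metadata"]]).format_row())
print("value plots:", hk.summarize([pairs["value"]]).format_row())
```

prints

```
MD: -7.5 PSD: 3.65 VFI: 84
strategy: SITA-Faster field: 24-2 eye: OD
raw row 4: ['30', '28', '24', '24', '23', '20', '20', 'BS', '24', '']
metadata: 0/17 errors, 0.0% (95% CI 0.0-19.5), median 0 (Q1 0, Q3 0) per report
value plots: 0/158 errors, 0.0% (95% CI 0.0-2.3), median 0 (Q1 0, Q3 0) per report
```

The extracted mean deviation (−7.5 dB) and every plot cell — including
the `BS` blind-spot triangle at the temporal midline and the trailing
empty cell outside the 24-2 pattern — equal the generated ground truth,
so both error rates are 0 with their exact binomial upper bounds.

## Command line

```sh
vf fixtures out/ --version V2 --n 10 --seed 1 --noise CLEAN  # PNG + truth JSON
vf extract out/v2_clean_00001.png --json report.json
vf batch out/ extracted/                                     # JSON + TSV per page
vf validate extracted/ out/ --report validation.json
```

## Layout and template calibration

Region maps (one JSON per layout version), label-anchor patterns, test
point masks and the DICOM tag map are shipped as editable configuration
under `src/hvfkit/config/`; `vf extract --layout-file` points the
pipeline at a recalibrated map. Recognition templates default to the
shipped glyph set and can be replaced by device-font rasters via
`TemplateSet.from_dir`.
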