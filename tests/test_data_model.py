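"""Field normalization, JSON serialization and delimited export."""

import datetime

import pytest
from hypothesis import given, settings, strategies as st

from hvfkit.data_model import (
    ABSENT,
    HvfMetadata,
    HvfReport,
    ParseError,
    PlotGrid,
    SchemaVersionError,
    ValueCell,
    canonical_text,
    delimited_header,
    deserialize_json,
    normalize_field,
    serialize_json,
    to_delimited,
)
from hvfkit.layout_registry import METADATA_FIELDS

from conftest import make_report


@pytest.mark.parametrize(
    "field_id,raw,expected",
    [
        ("mean_deviation", "-0.47 dB", -0.47),
        ("mean_deviation", "−0.47 dB", -0.47),  # unicode minus
        ("laterality", "Left", "OS"),
        ("laterality", "OD", "OD"),
        ("test_duration", "06:54", "06:54"),
        ("test_duration", "6:54", "06:54"),
        ("vfi", "garbage##", ABSENT),
        ("vfi", "94%", 94),
        ("date_of_birth", "11-15-1941", datetime.date(1941, 11, 15)),
        ("date_of_birth", "11/15/1941", datetime.date(1941, 11, 15)),
        ("date_of_birth", "1941-11-15", datetime.date(1941, 11, 15)),
        ("field_size", "Central 24-2", "24-2"),
        ("strategy", "SITA Standard", "SITA-Standard"),
        ("strategy", "sita-faster", "SITA-Faster"),
        ("fixation_loss", "2/15", "2/15"),
        ("false_positive_rate", "2 %", "2%"),
        ("false_positive_rate", "1/13", "1/13"),
        ("pupil_diameter", "4.1 MM", 4.1),
        ("foveal_sensitivity", "OFF", ABSENT),
        ("foveal_sensitivity", "<0", ABSENT),  # below-threshold is not 0
        ("foveal_sensitivity", "33 DB", 33.0),
        ("pattern_standard_deviation", "2.92 dB", 2.92),
        ("refraction", "-0.75DS +1.25DC X 88", "-0.75DS +1.25DC X 88"),
        ("name", "Smith, John", "SMITH, JOHN"),
    ],
)
def test_normalize_field_examples(field_id, raw, expected):
    assert normalize_field(field_id, raw) == expected


def test_normalize_field_contracts():
    with pytest.raises(KeyError):
        normalize_field("no_such_field", "x")
    with pytest.raises(TypeError):
        normalize_field("name", None)
    for fid in METADATA_FIELDS:
        assert normalize_field(fid, "   ") is ABSENT


@pytest.mark.parametrize("field_id", METADATA_FIELDS)
def test_normalize_field_idempotent_through_canonical_text(field_id):
    samples = {
        "name": ["Smith, John"], "patient_id": ["43150443"],
        "date_of_birth": ["11-15-1941"], "test_date": ["03/04/2019"],
        "laterality": ["Right", "os"], "foveal_sensitivity": ["36 dB"],
        "false_positive_rate": ["2%", "1/13"],
        "false_negative_rate": ["0 %"], "fixation_loss": ["2/15"],
        "test_duration": ["6:54"], "field_size": ["24-2"],
        "strategy": ["SITA Fast"], "pupil_diameter": ["4.7 mm"],
        "refraction": ["-2.00DS +3.00DC X 175"], "mean_deviation": ["-0.47 dB"],
        "pattern_standard_deviation": ["4.50 dB"], "vfi": ["99%"],
    }[field_id]
    for raw in samples:
        once = normalize_field(field_id, raw)
        assert once is not ABSENT
        again = normalize_field(field_id, canonical_text(field_id, once))
        assert again == once


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_json_round_trip_is_identity(seed):
    report = make_report(seed % 12, seed_base=seed)
    assert deserialize_json(serialize_json(report)) == report


def test_serialization_is_deterministic():
    report = make_report(3)
    assert serialize_json(report) == serialize_json(report)


def test_all_empty_pd_grids_survive_round_trip():
    report = make_report(5, include_pd=False)
    assert report.pd_value.nonempty_positions() == set()
    back = deserialize_json(serialize_json(report))
    assert back.pd_value.nonempty_positions() == set()
    assert back.pd_perc.nonempty_positions() == set()


def test_eleven_row_grid_is_a_parse_error():
    import json

    doc = json.loads(serialize_json(make_report(0)))
    doc["plots"]["raw"].append([None] * 10)
    with pytest.raises(ParseError, match="raw"):
        deserialize_json(json.dumps(doc))


def test_wrong_schema_version_is_rejected():
    import json

    doc = json.loads(serialize_json(make_report(0)))
    doc["schema_version"] = "99.0"
    with pytest.raises(SchemaVersionError):
        deserialize_json(json.dumps(doc))


def test_minimal_document_yields_absent_fields():
    import json

    doc = {
        "schema": "hvfkit-report",
        "schema_version": "1.0",
        "metadata": {"laterality": "OD"},
        "plots": {k: [[None] * 10 for _ in range(10)]
                  for k in ("raw", "td_value", "pd_value", "td_perc", "pd_perc")},
    }
    report = deserialize_json(json.dumps(doc))
    assert report.metadata.laterality == "OD"
    for fid in METADATA_FIELDS:
        if fid != "laterality":
            assert report.metadata.get(fid) is ABSENT


def test_value_cell_contracts():
    with pytest.raises(ValueError):
        ValueCell("NUMBER", 51)
    with pytest.raises(ValueError):
        ValueCell("EMPTY", 3)
    assert ValueCell("BELOW_THRESHOLD").token() == "<0"


def test_grid_must_be_ten_by_ten():
    with pytest.raises(ValueError):
        PlotGrid("RAW", tuple(tuple(ValueCell() for _ in range(10))
                              for _ in range(9)))


def test_metadata_accessors():
    md = HvfMetadata(fixation_loss="2/15", test_duration="06:54")
    assert md.fixation_loss_fraction == (2, 15)
    assert md.test_duration_seconds == 6 * 60 + 54


def test_delimited_export_shape_and_signs():
    reports = [make_report(i) for i in range(3)]
    table = to_delimited(reports)
    lines = table.strip("\n").split("\n")
    assert len(lines) == 4  # header + one row per report
    ncols = 2 + 17 + 5 * 100
    assert all(len(line.split("\t")) == ncols for line in lines)
    assert len(delimited_header()) == ncols
    # a negative deviation value survives as literal text
    neg = next(
        c.token()
        for r in reports
        for row in r.td_value.cells
        for c in row
        if c.kind == "NUMBER" and c.value < 0
    )
    assert neg.startswith("-") and neg in lines[1] + lines[2] + lines[3]
    with pytest.raises(ValueError):
        to_delimited([])


def test_report_consistency_violations_are_reported_not_fatal():
    report = make_report(1)
    broken = HvfReport(
        metadata=report.metadata,
        raw=report.raw,
        td_value=report.td_value.with_cell(4, 4, ValueCell()),
        pd_value=report.pd_value,
        td_perc=report.td_perc,
        pd_perc=report.pd_perc,
    )
    assert any("td_value" in p for p in broken.consistency_violations())
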