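"""Ophthalmic visual field (OPV) DICOM ingest.

Reads OPV datasets into :class:`~hvfkit.data_model.HvfReport`, the
reference-data pathway used for validation, and writes minimal OPV
fixtures for testing.  Attribute mapping is editable configuration
(``config/opv_tags.json``); only public tags are used.

Per-point placement converts each test point's angular coordinates to
grid indices: ``col = x/spacing + 4.5`` and ``row = 4.5 - y/spacing``
(spacing 6 degrees for 24-2/30-2, 2 degrees for 10-2), with x positive
temporal for OD and mirrored for OS — the standard HFA chart geometry,
adopted here as a documented convention.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import io
import json
import re
from functools import lru_cache
from importlib import resources

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian

from .data_model import (
    ABSENT,
    HvfMetadata,
    HvfReport,
    PercentileCell,
    PlotGrid,
    ValueCell,
)

OPV_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.80.1"

_FIELD_EXTENT = {"10-2": 20.0, "24-2": 54.0, "30-2": 60.0}
_PERC_PROB = {"P5": 5.0, "P2": 2.0, "P1": 1.0, "P05": 0.5}
_PROB_PERC = {v: k for k, v in _PERC_PROB.items()}


class NotOpv(ValueError):
    """Parsed as DICOM, but carries no visual field test point data."""


class DicomParseError(ValueError):
    """Input is not a parseable DICOM dataset."""


@lru_cache(maxsize=1)
def load_tag_map() -> dict:
    return json.loads(
        (resources.files("hvfkit.config") / "opv_tags.json").read_text()
    )


def _spacing(field_size: str | None) -> float:
    return 2.0 if field_size == "10-2" else 6.0


def _grid_to_deg(r: int, c: int, spacing: float, laterality: str) -> tuple[float, float]:
    x = (c - 4.5) * spacing
    if laterality == "OS":
        x = -x
    return x, (4.5 - r) * spacing


def _deg_to_grid(x: float, y: float, spacing: float, laterality: str) -> tuple[int, int]:
    if laterality == "OS":
        x = -x
    return int(round(4.5 - y / spacing)), int(round(x / spacing + 4.5))


# --- writing --------------------------------------------------------------


def write_opv_fixture(report: HvfReport) -> bytes:
    """Serialize a report as a minimal explicit-VR little-endian OPV file.

    Round-trip contract: ``read_opv(write_opv_fixture(R))`` equals R on
    every mapped field.  Free-text refraction that does not follow the
    ``{sph}DS {cyl}DC X {axis}`` convention is not representable and
    reads back ABSENT.
    """
    md = report.metadata
    ds = Dataset()
    ds.SOPClassUID = OPV_SOP_CLASS
    digest = hashlib.sha1(repr(report).encode()).hexdigest()[:16]
    ds.SOPInstanceUID = "2.25." + str(int(digest, 16))
    ds.Modality = "OPV"

    if md.name is not ABSENT:
        ds.PatientName = md.name.replace(", ", "^")
    if md.patient_id is not ABSENT:
        ds.PatientID = md.patient_id
    if md.date_of_birth is not ABSENT:
        ds.PatientBirthDate = md.date_of_birth.strftime("%Y%m%d")
    if md.test_date is not ABSENT:
        ds.StudyDate = md.test_date.strftime("%Y%m%d")
    if md.laterality is not ABSENT:
        ds.MeasurementLaterality = "R" if md.laterality == "OD" else "L"
    if md.foveal_sensitivity is not ABSENT:
        ds.FovealSensitivityMeasured = "YES"
        ds.FovealSensitivity = md.foveal_sensitivity
    if md.test_duration is not ABSENT:
        ds.VisualFieldTestDuration = float(md.test_duration_seconds)
    if md.strategy is not ABSENT:
        ds.ProtocolName = md.strategy
    if md.pupil_diameter is not ABSENT:
        ds.PupilSize = md.pupil_diameter
    if md.mean_deviation is not ABSENT:
        ds.GlobalDeviationFromNormal = md.mean_deviation
    if md.pattern_standard_deviation is not ABSENT:
        ds.LocalizedDeviationFromNormal = md.pattern_standard_deviation
    if md.field_size is not ABSENT:
        ds.VisualFieldHorizontalExtent = _FIELD_EXTENT[md.field_size]
        ds.VisualFieldVerticalExtent = _FIELD_EXTENT[md.field_size]

    def _rate_item(text: str, kind: str) -> Dataset | None:
        item = Dataset()
        m = re.fullmatch(r"(\d+(?:\.\d+)?)%", text)
        if m:
            setattr(item, f"False{kind}Estimate", float(m.group(1)))
            setattr(item, f"False{kind}EstimateFlag", "YES")
            return item
        m = re.fullmatch(r"(\d+)/(\d+)", text)
        if m:
            setattr(item, f"False{kind}Quantity", int(m.group(1)))
            setattr(item, f"{'Positive' if kind == 'Positives' else 'Negative'}"
                          "CatchTrialsQuantity", int(m.group(2)))
            return item
        return None

    catch = []
    if md.false_positive_rate is not ABSENT:
        item = _rate_item(md.false_positive_rate, "Positives")
        if item is not None:
            catch.append(item)
    if md.false_negative_rate is not ABSENT:
        item = _rate_item(md.false_negative_rate, "Negatives")
        if item is not None:
            catch.append(item)
    if catch:
        ds.VisualFieldCatchTrialSequence = catch

    if md.fixation_loss is not ABSENT:
        num, den = md.fixation_loss_fraction
        fx = Dataset()
        fx.FixationCheckedQuantity = den
        fx.PatientNotProperlyFixatedQuantity = num
        ds.FixationSequence = [fx]

    if md.refraction is not ABSENT:
        m = re.fullmatch(
            r"([-+]?\d+(?:\.\d+)?)DS ([-+]?\d+(?:\.\d+)?)DC X (\d+)",
            md.refraction,
        )
        if m:
            rx = Dataset()
            rx.SphericalLensPower = float(m.group(1))
            rx.CylinderLensPower = float(m.group(2))
            rx.CylinderAxis = float(m.group(3))
            ds.RefractiveParametersUsedOnPatientSequence = [rx]

    if md.vfi is not ABSENT:
        concept = Dataset()
        concept.CodeValue = "VFI"
        concept.CodingSchemeDesignator = "99HVFKIT"
        concept.CodeMeaning = "Visual Field Index"
        obs = Dataset()
        obs.ConceptNameCodeSequence = [concept]
        obs.NumericValue = str(md.vfi)
        idx = Dataset()
        idx.DataObservationSequence = [obs]
        ds.VisualFieldGlobalResultsIndexSequence = [idx]

    spacing = _spacing(md.field_size)
    laterality = md.laterality if md.laterality is not ABSENT else "OD"
    points = []
    for r in range(10):
        for c in range(10):
            raw = report.raw.cells[r][c]
            if raw.is_empty:
                continue
            pt = Dataset()
            x, y = _grid_to_deg(r, c, spacing, laterality)
            pt.VisualFieldTestPointXCoordinate = x
            pt.VisualFieldTestPointYCoordinate = y
            if raw.kind == "BLIND_SPOT":
                pt.StimulusResults = "NOT SEEN"
            elif raw.kind == "BELOW_THRESHOLD":
                pt.StimulusResults = "NOT SEEN"
                pt.SensitivityValue = 0.0
            else:
                pt.StimulusResults = "SEEN"
                pt.SensitivityValue = float(raw.value)
            td = report.td_value.cells[r][c]
            if td.kind == "NUMBER":
                pt.AgeCorrectedSensitivityDeviationValue = float(td.value)
                perc = report.td_perc.cells[r][c]
                if perc.kind in _PERC_PROB:
                    pt.AgeCorrectedSensitivityDeviationProbabilityValue = \
                        _PERC_PROB[perc.kind]
            pd_ = report.pd_value.cells[r][c]
            if pd_.kind == "NUMBER":
                pt.GeneralizedDefectCorrectedSensitivityDeviationValue = \
                    float(pd_.value)
                perc = report.pd_perc.cells[r][c]
                if perc.kind in _PERC_PROB:
                    pt.GeneralizedDefectCorrectedSensitivityDeviationProbabilityValue = \
                        _PERC_PROB[perc.kind]
            points.append(pt)
    ds.VisualFieldTestPointSequence = points

    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = OPV_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.file_meta = meta
    buf = io.BytesIO()
    pydicom.dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


# --- reading --------------------------------------------------------------


def _read_date(value: str) -> _dt.date | None:
    try:
        return _dt.datetime.strptime(value, "%Y%m%d").date()
    except (TypeError, ValueError):
        return ABSENT


def _fmt_rate(v: float) -> str:
    return f"{v:g}%"


def read_opv(source) -> HvfReport:
    """Read an OPV DICOM dataset (bytes, path or file object) into a report.

    Missing optional attributes map to ABSENT; a dataset without the
    per-point test sequence raises :class:`NotOpv`.
    """
    if isinstance(source, (bytes, bytearray)):
        source = io.BytesIO(source)
    try:
        ds = pydicom.dcmread(source)
    except (InvalidDicomError, EOFError, OSError) as e:
        if isinstance(e, OSError) and not isinstance(e, InvalidDicomError):
            raise
        raise DicomParseError(f"not a DICOM dataset: {e}") from None
    tags = load_tag_map()
    if tags["point_sequence"] not in ds:
        raise NotOpv("dataset has no visual field test point sequence")

    values: dict = {}
    if "PatientName" in ds and str(ds.PatientName):
        values["name"] = str(ds.PatientName).replace("^", ", ")
    if "PatientID" in ds and ds.PatientID:
        values["patient_id"] = str(ds.PatientID)
    if "PatientBirthDate" in ds:
        d = _read_date(ds.PatientBirthDate)
        if d is not ABSENT:
            values["date_of_birth"] = d
    if "StudyDate" in ds:
        d = _read_date(ds.StudyDate)
        if d is not ABSENT:
            values["test_date"] = d
    laterality = ABSENT
    if "MeasurementLaterality" in ds:
        laterality = {"R": "OD", "L": "OS", "OD": "OD", "OS": "OS"}.get(
            str(ds.MeasurementLaterality)
        )
    if laterality is not ABSENT:
        values["laterality"] = laterality
    if "FovealSensitivity" in ds:
        values["foveal_sensitivity"] = round(float(ds.FovealSensitivity), 1)
    if "VisualFieldTestDuration" in ds:
        sec = int(round(float(ds.VisualFieldTestDuration)))
        values["test_duration"] = f"{sec // 60:02d}:{sec % 60:02d}"
    if "ProtocolName" in ds:
        from .data_model import normalize_field

        strat = normalize_field("strategy", str(ds.ProtocolName))
        if strat is not ABSENT:
            values["strategy"] = strat
    if "PupilSize" in ds:
        values["pupil_diameter"] = round(float(ds.PupilSize), 1)
    if "GlobalDeviationFromNormal" in ds:
        values["mean_deviation"] = round(float(ds.GlobalDeviationFromNormal), 2)
    if "LocalizedDeviationFromNormal" in ds:
        values["pattern_standard_deviation"] = round(
            float(ds.LocalizedDeviationFromNormal), 2
        )
    field_size = ABSENT
    if "VisualFieldHorizontalExtent" in ds:
        ext = float(ds.VisualFieldHorizontalExtent)
        field_size = min(_FIELD_EXTENT, key=lambda k: abs(_FIELD_EXTENT[k] - ext))
    if field_size is not ABSENT:
        values["field_size"] = field_size

    for item in ds.get("VisualFieldCatchTrialSequence", []):
        if "FalsePositivesEstimate" in item:
            values["false_positive_rate"] = _fmt_rate(
                float(item.FalsePositivesEstimate))
        elif "FalsePositivesQuantity" in item:
            values["false_positive_rate"] = (
                f"{int(item.FalsePositivesQuantity)}/"
                f"{int(item.PositiveCatchTrialsQuantity)}")
        if "FalseNegativesEstimate" in item:
            values["false_negative_rate"] = _fmt_rate(
                float(item.FalseNegativesEstimate))
        elif "FalseNegativesQuantity" in item:
            values["false_negative_rate"] = (
                f"{int(item.FalseNegativesQuantity)}/"
                f"{int(item.NegativeCatchTrialsQuantity)}")
    for item in ds.get("FixationSequence", []):
        if "FixationCheckedQuantity" in item and \
                "PatientNotProperlyFixatedQuantity" in item:
            values["fixation_loss"] = (
                f"{int(item.PatientNotProperlyFixatedQuantity)}/"
                f"{int(item.FixationCheckedQuantity)}")
    for item in ds.get("RefractiveParametersUsedOnPatientSequence", []):
        if "SphericalLensPower" in item:
            values["refraction"] = (
                f"{float(item.SphericalLensPower):+.2f}DS "
                f"{float(item.CylinderLensPower):+.2f}DC "
                f"X {int(item.CylinderAxis)}")
    for idx in ds.get("VisualFieldGlobalResultsIndexSequence", []):
        for obs in idx.get("DataObservationSequence", []):
            concepts = obs.get("ConceptNameCodeSequence", [])
            if concepts and concepts[0].get("CodeValue") == "VFI":
                values["vfi"] = int(round(float(obs.NumericValue)))

    metadata = HvfMetadata(**values)
    spacing = _spacing(field_size if field_size is not ABSENT else None)
    lat = laterality if laterality is not ABSENT else "OD"

    raw = PlotGrid.empty("RAW")
    td = PlotGrid.empty("TD_VALUE")
    pd_ = PlotGrid.empty("PD_VALUE")
    tdp = PlotGrid.empty("TD_PERC")
    pdp = PlotGrid.empty("PD_PERC")
    for pt in ds[tags["point_sequence"]]:
        r, c = _deg_to_grid(
            float(pt.VisualFieldTestPointXCoordinate),
            float(pt.VisualFieldTestPointYCoordinate),
            spacing, lat,
        )
        if not (0 <= r <= 9 and 0 <= c <= 9):
            raise NotOpv(f"test point outside the 10x10 grid at row {r}, col {c}")
        seen = str(pt.get("StimulusResults", "SEEN"))
        if "SensitivityValue" not in pt:
            raw = raw.with_cell(r, c, ValueCell("BLIND_SPOT"))
            continue
        if seen == "NOT SEEN" and float(pt.SensitivityValue) == 0.0:
            raw = raw.with_cell(r, c, ValueCell("BELOW_THRESHOLD"))
        else:
            raw = raw.with_cell(
                r, c, ValueCell("NUMBER", int(round(float(pt.SensitivityValue))))
            )
        if "AgeCorrectedSensitivityDeviationValue" in pt:
            td = td.with_cell(r, c, ValueCell(
                "NUMBER",
                int(round(float(pt.AgeCorrectedSensitivityDeviationValue)))))
            prob = pt.get("AgeCorrectedSensitivityDeviationProbabilityValue")
            kind = _PROB_PERC.get(float(prob), "NORMAL") if prob is not None \
                else "NORMAL"
            tdp = tdp.with_cell(r, c, PercentileCell(kind))
        if "GeneralizedDefectCorrectedSensitivityDeviationValue" in pt:
            pd_ = pd_.with_cell(r, c, ValueCell(
                "NUMBER",
                int(round(float(
                    pt.GeneralizedDefectCorrectedSensitivityDeviationValue)))))
            prob = pt.get(
                "GeneralizedDefectCorrectedSensitivityDeviationProbabilityValue")
            kind = _PROB_PERC.get(float(prob), "NORMAL") if prob is not None \
                else "NORMAL"
            pdp = pdp.with_cell(r, c, PercentileCell(kind))

    return HvfReport(
        metadata=metadata, raw=raw, td_value=td, pd_value=pd_,
        td_perc=tdp, pd_perc=pdp, source_kind="DICOM",
        source=str(ds.get("SOPInstanceUID", "")),
    )
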