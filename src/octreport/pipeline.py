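"""End-to-end orchestration: image -> classified layout -> routed regions ->
recognized values / findings -> longitudinal records -> CSV / CDM rows.

One input image yields exactly one record (two for bilateral layouts, one per
eye) or one error — never both.  Extraction failures on individual fields are
recorded as per-record warnings, never silent zeros.  Dates are normalized to
ISO-8601 using the catalog's configured on-page format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field, replace
from datetime import datetime
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .area_explorer import ContentClass, route_region
from .finding_activity import (
    ACTIVITY_DISPLAY,
    FindingModel,
    FindingResult,
    VisitObservation,
    classify_finding,
    derive_activity,
)
from .layout_config import FieldKind, LayoutCatalog
from .report_classifier import classify_report
from .value_reader import (
    Measurement,
    MISSING_MARKERS,
    ParseError,
    Recognition,
    RecognitionFailure,
    ReferenceRecognizer,
    allowed_chars_from_pattern,
    parse_value,
)

__all__ = [
    "ExtractedRecord",
    "CdmMeasurementRow",
    "UnreadableFileError",
    "process_image",
    "assign_activity",
    "write_csv",
    "read_csv",
    "to_cdm_rows",
    "export_crops",
    "default_concept_map",
    "load_concept_map",
    "measurement_columns",
    "canonical_field_name",
]

CMT_FIELD = "central_macular_thickness"

_EYE_PREFIXES = {"od_": "right", "os_": "left"}


class UnreadableFileError(RuntimeError):
    pass


@dataclass
class ExtractedRecord:
    patient_id: str
    visit_date: str
    type_id: str
    laterality: str | None  # right/left; None only when undetermined
    measurements: list[Measurement]
    findings: FindingResult | None = None
    activity: str | None = None
    source_path: str = ""
    warnings: list[str] = dc_field(default_factory=list)
    raw_texts: dict[str, str] = dc_field(default_factory=dict, compare=False)
    tomogram_crops: dict[str, np.ndarray] = dc_field(default_factory=dict,
                                                     compare=False, repr=False)

    def measurement(self, name: str) -> Measurement | None:
        for m in self.measurements:
            if m.name == name:
                return m
        return None


@dataclass(frozen=True)
class CdmMeasurementRow:
    person_id: str
    measurement_concept_id: int
    measurement_date: str
    value_as_number: float
    unit_concept_id: int
    unit_source_value: str
    measurement_source_value: str
    source_file: str


def canonical_field_name(name: str) -> str:
    """Strip per-eye prefixes so both eyes share one measurement column."""
    for prefix in _EYE_PREFIXES:
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


# ---------------------------------------------------------------------------
# single image -> record(s)

def _load_page(path) -> np.ndarray:
    p = Path(path)
    try:
        with Image.open(p) as img:
            return np.asarray(img.convert("L"))
    except FileNotFoundError:
        raise
    except Exception as e:
        raise UnreadableFileError(f"cannot read image file {p}: {e}") from e


def _normalize_date(text: str, fmt: str) -> tuple[str, bool]:
    try:
        return datetime.strptime(text.strip(), fmt).date().isoformat(), True
    except ValueError:
        return text.strip(), False


_RETRY_SCALES = (1.5, 0.75, 2.0)

logger = __import__("logging").getLogger("octreport.pipeline")


def _text_is_valid(field, text: str, date_fmt: str) -> bool:
    """Does a recognized string satisfy the field's declared shape?"""
    if not text:
        return False
    if field.kind == FieldKind.NUMERIC:
        if text.strip() in MISSING_MARKERS:
            return True
        return re.fullmatch(field.pattern or r"-?\d+(?:\.\d+)?", text.strip()) is not None
    if field.kind == FieldKind.DATE:
        return _normalize_date(text, date_fmt)[1]
    if field.pattern:
        return re.fullmatch(field.pattern, text.strip()) is not None
    return True


def _reread_invalid(reader, field, crop, allowed, date_fmt: str,
                    first: Recognition) -> Recognition:
    """Pattern-validated re-read at alternative scales.

    A recognition that violates the field's declared shape (wrong length,
    impossible structure) is re-attempted on deterministically rescaled
    views of the crop; the first pattern-conforming result wins.  Recognizer
    mistakes are brittle to resampling, so a second view usually recovers
    the true string; if none conforms, the original read stands.
    """
    for scale in _RETRY_SCALES:
        h, w = crop.shape[:2]
        variant = np.asarray(Image.fromarray(crop).resize(
            (max(int(w * scale), 8), max(int(h * scale), 8)), Image.BILINEAR))
        try:
            try:
                rec = reader.recognize(variant, allowed=allowed)
            except TypeError:
                rec = reader.recognize(variant)
        except RecognitionFailure:
            continue
        if _text_is_valid(field, rec.text, date_fmt):
            logger.info("field %r: re-read at scale %.2f recovered %r "
                        "(first read %r)", field.name, scale, rec.text, first.text)
            return rec
    return first


def _field_alphabet(field, charset: str, date_fmt: str) -> str | None:
    """Permitted characters for a field (constrained decoding).

    Numeric fields decode over their pattern's character class plus the dash
    placeholder; dates over digits plus the date format's literal separators;
    text fields over their pattern's class when one is declared.
    """
    if field.kind == FieldKind.NUMERIC:
        base = allowed_chars_from_pattern(field.pattern, charset)
        if base is None:
            base = "".join(c for c in charset if c in "0123456789.-")
        extra = "".join(m for m in "".join(MISSING_MARKERS) if m in charset)
        return "".join(dict.fromkeys(base + extra))
    if field.kind == FieldKind.DATE:
        lits = set("0123456789")
        i = 0
        while i < len(date_fmt):
            if date_fmt[i] == "%":
                i += 2
            else:
                lits.add(date_fmt[i])
                i += 1
        return "".join(c for c in charset if c in lits) or None
    return allowed_chars_from_pattern(field.pattern, charset)


def process_image(path, catalog: LayoutCatalog, ocr_model=None,
                  finding_model: FindingModel | None = None) -> list[ExtractedRecord]:
    """Run the full per-image pipeline.

    ``ocr_model`` is any object with ``recognize(crop) -> Recognition``
    (a trained :class:`~octreport.value_reader.OcrModel` or the deterministic
    :class:`~octreport.value_reader.ReferenceRecognizer`); None selects the
    reference recognizer.  Bilateral layouts yield one record per eye.
    """
    page = _load_page(path) if not isinstance(path, np.ndarray) else path
    src = str(path) if not isinstance(path, np.ndarray) else ""
    reader = ocr_model if ocr_model is not None else ReferenceRecognizer(catalog.charset)
    result = classify_report(page, catalog)
    layout = catalog[result.type_id]
    eps = float(catalog.setting("area_explorer.ink_epsilon"))
    fill = float(catalog.setting("area_explorer.tomogram_fill"))
    date_fmt = layout.date_format or str(catalog.setting("date_format"))

    routed = [route_region(page, f, eps, fill, src) for f in layout.fields]
    warnings: list[str] = []
    raw_texts: dict[str, str] = {}
    tomo_crops: dict[str, np.ndarray] = {}

    # recognize all text-bearing crops (batched when the backend supports it)
    text_regions = [r for r in routed if r.field.kind != FieldKind.TOMOGRAM]
    recs: dict[str, Recognition] = {}
    crops = [r.crop for r in text_regions]
    alphabets = [_field_alphabet(r.field, catalog.charset, date_fmt)
                 for r in text_regions]
    if hasattr(reader, "recognize_crops"):
        results = reader.recognize_crops(crops, alphabets)
    else:
        results = []
        for r, crop, chars in zip(text_regions, crops, alphabets):
            if r.content_class == ContentClass.EMPTY:
                results.append(Recognition("", 0.0))
                continue
            try:
                try:
                    results.append(reader.recognize(crop, allowed=chars))
                except TypeError:  # recognizers without constrained decoding
                    results.append(reader.recognize(crop))
            except RecognitionFailure as e:
                warnings.append(f"{r.field.name}: recognition failed ({e})")
                results.append(Recognition("", 0.0))
    for r, rec, chars in zip(text_regions, results, alphabets):
        if r.content_class != ContentClass.EMPTY and \
                not _text_is_valid(r.field, rec.text, date_fmt):
            rec = _reread_invalid(reader, r.field, r.crop, chars, date_fmt, rec)
        raw_texts[r.field.name] = rec.text
        recs[r.field.name] = rec
        if r.content_class == ContentClass.EMPTY and r.field.kind != FieldKind.TOMOGRAM:
            warnings.append(f"{r.field.name}: region is empty")

    # findings from tomogram panels (max probability across panels)
    findings: FindingResult | None = None
    for r in routed:
        if r.field.kind == FieldKind.TOMOGRAM:
            tomo_crops[r.field.name] = r.crop
    if finding_model is not None and tomo_crops:
        agg: dict[str, float] = {}
        for name, crop in tomo_crops.items():
            try:
                fr = classify_finding(crop, finding_model)
            except ValueError as e:
                warnings.append(f"{name}: finding classification skipped ({e})")
                continue
            for k, p in fr.probabilities.items():
                agg[k] = max(agg.get(k, 0.0), p)
        if agg:
            findings = FindingResult.from_probabilities(agg)

    # page metadata
    patient_id = raw_texts.get("patient_id", "").strip()
    visit_date = ""
    for f in layout.fields:
        if f.kind == FieldKind.DATE:
            visit_date, ok = _normalize_date(recs[f.name].text, date_fmt)
            if not ok and recs[f.name].text:
                warnings.append(f"{f.name}: cannot parse date {recs[f.name].text!r}")
            break
    lat_text = raw_texts.get("laterality", "").strip().upper()
    page_laterality = {"RIGHT": "right", "LEFT": "left"}.get(lat_text)
    if "laterality" in raw_texts and page_laterality is None:
        warnings.append(f"laterality: unrecognized value {lat_text!r}")

    bilateral = any(f.eye for f in layout.fields)
    eyes = ("right", "left") if bilateral else (page_laterality,)

    records: list[ExtractedRecord] = []
    for eye in eyes:
        measurements: list[Measurement] = []
        for r in routed:
            f = r.field
            if f.kind != FieldKind.NUMERIC:
                continue
            if bilateral and f.eye is not None and f.eye != eye:
                continue
            name = canonical_field_name(f.name)
            if r.content_class == ContentClass.EMPTY:
                measurements.append(Measurement(name, None, f.unit, ""))
                continue
            try:
                m = parse_value(recs[f.name], f)
                measurements.append(replace(m, name=name))
            except ParseError as e:
                warnings.append(f"{f.name}: {e}")
        records.append(ExtractedRecord(
            patient_id=patient_id, visit_date=visit_date, type_id=layout.type_id,
            laterality=eye, measurements=measurements, findings=findings,
            source_path=src, warnings=list(warnings), raw_texts=dict(raw_texts),
            tomogram_crops=dict(tomo_crops)))
    return records


# ---------------------------------------------------------------------------
# longitudinal assembly

def assign_activity(records: list[ExtractedRecord],
                    threshold: float | None = None,
                    catalog: LayoutCatalog | None = None) -> list[ExtractedRecord]:
    """Derive disease-activity labels within each (patient, laterality) series."""
    if threshold is None:
        threshold = float(catalog.setting("activity.threshold")) if catalog else 0.25
    groups: dict[tuple, list[ExtractedRecord]] = {}
    for rec in records:
        groups.setdefault((rec.patient_id, rec.laterality), []).append(rec)
    for group in groups.values():
        group.sort(key=lambda r: r.visit_date)
        series = []
        for rec in group:
            m = rec.measurement(CMT_FIELD)
            series.append(VisitObservation(
                visit_date=rec.visit_date,
                cmt=None if m is None or m.is_missing else m.value,
                findings=rec.findings.labels if rec.findings else {}))
        for rec, label in zip(group, derive_activity(series, threshold)):
            rec.activity = label
    return records


# ---------------------------------------------------------------------------
# CSV

_FIXED_COLS = ["Patient ID", "Visit date", "Report type", "Laterality"]
_TAIL_COLS = ["Finding", "Activity", "Warnings", "Source"]


def measurement_columns(catalog: LayoutCatalog) -> list[str]:
    """Canonical numeric column names in catalog order (first occurrence wins)."""
    cols: list[str] = []
    for layout in catalog.layouts:
        for f in layout.numeric_fields:
            name = canonical_field_name(f.name)
            if name not in cols:
                cols.append(name)
    return cols


def _format_findings(fr: FindingResult | None) -> str:
    if fr is None:
        return ""
    parts = []
    for name in sorted(fr.labels):
        disp = name.replace("_", " ").capitalize()
        parts.append(f"{disp} ({'+' if fr.labels[name] else '-'})")
    return "; ".join(parts)


def _parse_findings(cell: str) -> FindingResult | None:
    cell = (cell or "").strip()
    if not cell:
        return None
    probs = {}
    for part in cell.split(";"):
        m = re.fullmatch(r"\s*(.+?)\s*\((\+|-)\)\s*", part)
        if not m:
            raise ValueError(f"cannot parse finding cell {cell!r}")
        name = m.group(1).strip().lower().replace(" ", "_")
        probs[name] = 1.0 if m.group(2) == "+" else 0.0
    return FindingResult.from_probabilities(probs)


def write_csv(records: list[ExtractedRecord], path,
              catalog: LayoutCatalog) -> pd.DataFrame:
    """One row per record, sorted by (patient, laterality, visit date).

    Measurement cells carry the recognized raw text (so missing values show
    the dash placeholder and absent columns stay empty); the column set is a
    pure function of the catalog, stable across runs.
    """
    if not records:
        raise ValueError("no records to write")
    mcols = measurement_columns(catalog)
    rows = []
    ordered = sorted(records, key=lambda r: (r.patient_id, r.laterality or "",
                                             r.visit_date))
    inv_activity = {v: k for k, v in ACTIVITY_DISPLAY.items()}  # noqa: F841
    for rec in ordered:
        row = {
            "Patient ID": rec.patient_id,
            "Visit date": rec.visit_date,
            "Report type": rec.type_id,
            "Laterality": (rec.laterality or "").capitalize(),
        }
        for name in mcols:
            m = rec.measurement(name)
            row[name] = m.raw_text if m is not None else ""
        row["Finding"] = _format_findings(rec.findings)
        row["Activity"] = ACTIVITY_DISPLAY.get(rec.activity, "") if rec.activity else ""
        row["Warnings"] = "|".join(rec.warnings)
        row["Source"] = rec.source_path
        rows.append(row)
    df = pd.DataFrame(rows, columns=_FIXED_COLS + mcols + _TAIL_COLS)
    df.to_csv(path, index=False)
    return df


def read_csv(path, catalog: LayoutCatalog) -> list[ExtractedRecord]:
    """Parse a results CSV back into records (inverse of :func:`write_csv`)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    units = {}
    for layout in catalog.layouts:
        for f in layout.numeric_fields:
            units.setdefault(canonical_field_name(f.name), f.unit)
    mcols = [c for c in measurement_columns(catalog) if c in df.columns]
    inv_activity = {v: k for k, v in ACTIVITY_DISPLAY.items()}
    records = []
    for _, row in df.iterrows():
        measurements = []
        for name in mcols:
            raw = row[name]
            if raw == "":
                continue
            try:
                value = float(raw)
            except ValueError:
                value = None
            measurements.append(Measurement(name, value, units[name], raw))
        lat = row["Laterality"].strip().lower() or None
        records.append(ExtractedRecord(
            patient_id=row["Patient ID"],
            visit_date=row["Visit date"],
            type_id=row["Report type"],
            laterality=lat,
            measurements=measurements,
            findings=_parse_findings(row["Finding"]),
            activity=inv_activity.get(row["Activity"]) if row["Activity"] else None,
            source_path=row["Source"],
            warnings=[w for w in row["Warnings"].split("|") if w],
        ))
    return records


# ---------------------------------------------------------------------------
# OMOP-CDM-shaped rows

def load_concept_map(path) -> dict[str, dict]:
    df = pd.read_csv(path, comment="#")
    out = {}
    for _, row in df.iterrows():
        out[str(row["field_name"])] = {
            "concept_id": int(row["concept_id"]),
            "unit_concept_id": int(row.get("unit_concept_id", 0) or 0),
        }
    return out


def default_concept_map() -> dict[str, dict]:
    ref = resources.files("octreport").joinpath("data/concept_map.csv")
    with resources.as_file(ref) as p:
        return load_concept_map(p)


def to_cdm_rows(records: list[ExtractedRecord],
                concept_map: dict[str, dict]) -> list[CdmMeasurementRow]:
    """One MEASUREMENT-shaped row per non-missing measurement.

    Every measurement field name must be mapped; unmapped names raise with
    the full list so the concept map can be fixed in one edit.
    """
    names = sorted({m.name for r in records for m in r.measurements})
    unmapped = [n for n in names if n not in concept_map]
    if unmapped:
        raise KeyError(f"concept map lacks entries for fields: {unmapped}")
    rows = []
    for rec in records:
        for m in rec.measurements:
            if m.is_missing:
                continue
            entry = concept_map[m.name]
            rows.append(CdmMeasurementRow(
                person_id=rec.patient_id,
                measurement_concept_id=entry["concept_id"],
                measurement_date=rec.visit_date,
                value_as_number=m.value,
                unit_concept_id=entry["unit_concept_id"],
                unit_source_value=m.unit,
                measurement_source_value=m.name,
                source_file=rec.source_path,
            ))
    return rows


def cdm_rows_to_frame(rows: list[CdmMeasurementRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# tomogram export

def export_crops(records: list[ExtractedRecord], out_dir) -> pd.DataFrame:
    """Write each tomogram crop as a lossless PNG plus a manifest CSV.

    Files are named ``{patient}_{date}_{laterality}_{field}.png``; re-export
    is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seen = set()
    for rec in sorted(records, key=lambda r: (r.patient_id, r.laterality or "",
                                              r.visit_date)):
        for name in sorted(rec.tomogram_crops):
            lat = rec.laterality or "ou"
            stem = f"{rec.patient_id}_{rec.visit_date}_{lat}_{name}"
            if stem in seen:
                continue
            seen.add(stem)
            fpath = out_dir / f"{stem}.png"
            Image.fromarray(rec.tomogram_crops[name]).save(fpath)
            rows.append({"file": fpath.name, "patient_id": rec.patient_id,
                         "visit_date": rec.visit_date, "laterality": lat,
                         "field": name, "source": rec.source_path})
    manifest = pd.DataFrame(rows, columns=["file", "patient_id", "visit_date",
                                           "laterality", "field", "source"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
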