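"""Layout catalog: where each measurement lives on each OCT report type.

A report produced by a given device software version follows one of a small
number of fixed page layouts.  The catalog maps each layout (``type_id``) to
a header region used for classification and a list of named field regions
(numeric values, dates, free text, or embedded tomogram panels).  Coordinates
are 0-based, half-open pixel rectangles ``(x0, y0, x1, y1)`` with x rightward
and y downward, so widths and heights are exact subtractions.

The catalog is a hand-editable YAML file; adapting the tool to a new device
or software version means editing coordinates, not code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "FieldKind",
    "FieldSpec",
    "ReportLayout",
    "LayoutCatalog",
    "CatalogError",
    "TYPE_IDS",
    "SCAN_ONLY_TYPES",
    "DEFAULT_CHARSET",
    "DEFAULT_SETTINGS",
    "load_catalog",
    "save_catalog",
    "default_catalog",
    "crop_region",
]

TYPE_IDS = (
    "rnfl_unilateral",
    "rnfl_bilateral",
    "macula_current",
    "macula_prev_current",
    "macula_scan_current",
    "macula_scan_prev_current",
)

#: Layouts that carry only tomographic panels (plus page metadata), no numerics.
SCAN_ONLY_TYPES = ("macula_scan_current", "macula_scan_prev_current")

FIELD_KINDS = ("numeric", "date", "text", "tomogram")

#: Characters the recognizer is expected to handle, in canonical order.
DEFAULT_CHARSET = "0123456789.-%/: ABCDEFGHIJKLMNOPQRSTUVWXYZ"

DEFAULT_SETTINGS: dict = {
    "classifier": {"accept_threshold": 0.7},
    "area_explorer": {"ink_epsilon": 0.005, "tomogram_fill": 0.20},
    "activity": {"threshold": 0.25},
    "findings": {"vocabulary": ["subretinal_fluid", "macular_edema"]},
    "date_format": "%Y-%m-%d",
}


class CatalogError(ValueError):
    """Raised when a catalog file violates the layout schema or invariants."""


class FieldKind:
    NUMERIC = "numeric"
    DATE = "date"
    TEXT = "text"
    TOMOGRAM = "tomogram"


Box = tuple[int, int, int, int]


@dataclass(frozen=True)
class FieldSpec:
    """One named rectangular region of a report page.

    ``pattern`` is a regular expression the recognized text must match for
    numeric fields (default: signed decimal).  ``eye`` tags per-eye fields on
    bilateral layouts (``right``/``left``); unilateral layouts leave it None
    and carry a ``laterality`` text field on the page instead.
    """

    name: str
    kind: str
    box: Box
    unit: str = ""
    pattern: str | None = None
    eye: str | None = None

    def __post_init__(self):
        if self.kind not in FIELD_KINDS:
            raise CatalogError(f"field {self.name!r}: unknown kind {self.kind!r}")
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise CatalogError(
                f"field {self.name!r}: degenerate box {self.box} (need x0<x1, y0<y1)")
        if self.kind != FieldKind.NUMERIC and self.unit:
            raise CatalogError(
                f"field {self.name!r}: unit {self.unit!r} on non-numeric kind")
        if self.eye not in (None, "right", "left"):
            raise CatalogError(f"field {self.name!r}: bad eye tag {self.eye!r}")
        if self.pattern is not None:
            try:
                re.compile(self.pattern)
            except re.error as e:
                raise CatalogError(f"field {self.name!r}: bad pattern: {e}") from e

    @property
    def width(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> int:
        return self.box[3] - self.box[1]


@dataclass(frozen=True)
class ReportLayout:
    type_id: str
    header_title: str
    header_box: Box
    page_size: tuple[int, int]
    fields: tuple[FieldSpec, ...]
    version_range: str = ""
    date_format: str = ""  # on-page date format; empty = catalog default

    def __post_init__(self):
        if self.type_id not in TYPE_IDS:
            raise CatalogError(f"unknown type_id {self.type_id!r}")
        w, h = self.page_size
        for f in (*self.fields, FieldSpec("header", "text", self.header_box)):
            x0, y0, x1, y1 = f.box
            if not (0 <= x0 and 0 <= y0 and x1 <= w and y1 <= h):
                raise CatalogError(
                    f"layout {self.type_id}: field {f.name!r} box {f.box} "
                    f"outside page {self.page_size}")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"layout {self.type_id}: duplicate field names {dup}")
        kinds = {f.kind for f in self.fields}
        if self.type_id in SCAN_ONLY_TYPES:
            if FieldKind.NUMERIC in kinds:
                raise CatalogError(
                    f"layout {self.type_id}: scan-only type must not carry numeric fields")
            if FieldKind.TOMOGRAM not in kinds:
                raise CatalogError(
                    f"layout {self.type_id}: scan-only type needs a tomogram field")
        else:
            if FieldKind.NUMERIC not in kinds:
                raise CatalogError(
                    f"layout {self.type_id}: needs at least one numeric field")

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def numeric_fields(self) -> tuple[FieldSpec, ...]:
        return tuple(f for f in self.fields if f.kind == FieldKind.NUMERIC)

    @property
    def tomogram_fields(self) -> tuple[FieldSpec, ...]:
        return tuple(f for f in self.fields if f.kind == FieldKind.TOMOGRAM)


@dataclass(frozen=True)
class LayoutCatalog:
    layouts: tuple[ReportLayout, ...]
    charset: str = DEFAULT_CHARSET
    settings: dict = field(default_factory=lambda: dict(DEFAULT_SETTINGS), compare=False)

    def __post_init__(self):
        ids = [l.type_id for l in self.layouts]
        if len(set(ids)) != len(ids):
            raise CatalogError(f"duplicate type_ids: {ids}")
        titles = [l.header_title for l in self.layouts]
        if len(set(titles)) != len(titles):
            dup = sorted({t for t in titles if titles.count(t) > 1})
            raise CatalogError(f"duplicate header titles: {dup}")
        if len(set(self.charset)) != len(self.charset):
            raise CatalogError("charset contains repeated characters")

    def __getitem__(self, type_id: str) -> ReportLayout:
        for l in self.layouts:
            if l.type_id == type_id:
                return l
        raise KeyError(type_id)

    def __contains__(self, type_id: str) -> bool:
        return any(l.type_id == type_id for l in self.layouts)

    @property
    def type_ids(self) -> tuple[str, ...]:
        return tuple(l.type_id for l in self.layouts)

    @property
    def is_complete(self) -> bool:
        return set(self.type_ids) == set(TYPE_IDS)

    def setting(self, dotted: str):
        """Fetch a settings value by dotted key, falling back to defaults."""
        node, fallback = self.settings, DEFAULT_SETTINGS
        for part in dotted.split("."):
            fallback = fallback.get(part, None) if isinstance(fallback, dict) else None
            if isinstance(node, dict) and part in node:
                node = node[part]
            else:
                node = fallback
                if node is None:
                    raise KeyError(dotted)
        return node


# ---------------------------------------------------------------------------
# serialization

def _field_to_dict(f: FieldSpec) -> dict:
    d = {"name": f.name, "kind": f.kind, "box": list(f.box)}
    if f.unit:
        d["unit"] = f.unit
    if f.pattern is not None:
        d["pattern"] = f.pattern
    if f.eye is not None:
        d["eye"] = f.eye
    return d


def _field_from_dict(d: dict, where: str) -> FieldSpec:
    try:
        return FieldSpec(
            name=str(d["name"]),
            kind=str(d["kind"]),
            box=tuple(int(v) for v in d["box"]),
            unit=str(d.get("unit", "")),
            pattern=d.get("pattern"),
            eye=d.get("eye"),
        )
    except KeyError as e:
        raise CatalogError(f"{where}: field missing key {e}") from e


def catalog_to_dict(catalog: LayoutCatalog) -> dict:
    return {
        "charset": catalog.charset,
        "settings": catalog.settings,
        "layouts": [
            {
                "type_id": l.type_id,
                "header_title": l.header_title,
                "header_box": list(l.header_box),
                "page_size": list(l.page_size),
                "version_range": l.version_range,
                **({"date_format": l.date_format} if l.date_format else {}),
                "fields": [_field_to_dict(f) for f in l.fields],
            }
            for l in catalog.layouts
        ],
    }


def catalog_from_dict(doc: dict) -> LayoutCatalog:
    if not isinstance(doc, dict) or "layouts" not in doc:
        raise CatalogError("catalog document must be a mapping with a 'layouts' list")
    layouts = []
    for entry in doc["layouts"]:
        tid = entry.get("type_id", "<missing type_id>")
        try:
            layout = ReportLayout(
                type_id=str(entry["type_id"]),
                header_title=str(entry["header_title"]),
                header_box=tuple(int(v) for v in entry["header_box"]),
                page_size=tuple(int(v) for v in entry["page_size"]),
                version_range=str(entry.get("version_range", "")),
                date_format=str(entry.get("date_format", "")),
                fields=tuple(
                    _field_from_dict(fd, f"layout {tid}") for fd in entry.get("fields", [])
                ),
            )
        except KeyError as e:
            raise CatalogError(f"layout {tid}: missing key {e}") from e
        layouts.append(layout)
    settings = doc.get("settings") or dict(DEFAULT_SETTINGS)
    return LayoutCatalog(
        layouts=tuple(layouts),
        charset=str(doc.get("charset", DEFAULT_CHARSET)),
        settings=settings,
    )


def load_catalog(path) -> LayoutCatalog:
    """Load and validate a layout catalog from a YAML (or JSON) file.

    Invalid entries are rejected with a :class:`CatalogError` naming the
    offending layout/field; nothing is silently repaired.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"catalog file not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise CatalogError(f"cannot parse catalog {p}: {e}") from e
    return catalog_from_dict(doc)


def save_catalog(catalog: LayoutCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(catalog_to_dict(catalog), fh, sort_keys=False,
                       allow_unicode=True)


def default_catalog() -> LayoutCatalog:
    """The catalog bundled with the package (matches the synthetic renderer)."""
    ref = resources.files("octreport").joinpath("data/default_catalog.yaml")
    with resources.as_file(ref) as p:
        return load_catalog(p)


# ---------------------------------------------------------------------------
# cropping

def crop_region(image: np.ndarray, box: Box) -> np.ndarray:
    """Copy the half-open rectangle ``(x0,y0,x1,y1)`` out of a raster page.

    The source is never modified; the result has shape ``(y1-y0, x1-x0)``
    (plus channels, if any).
    """
    arr = np.asarray(image)
    x0, y0, x1, y1 = box
    h, w = arr.shape[:2]
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"box {box} out of bounds for image {w}x{h}")
    return arr[y0:y1, x0:x1].copy()
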