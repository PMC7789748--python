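"""Route configured regions to the right consumer.

Numeric/text regions go to the Value Reader, tomographic regions to the
Finding Classifier, and blank regions are flagged as empty.  The content
class is detected from the crop itself (ink fraction and gray-level
statistics) and cross-checked against the catalog's declared kind: a
mismatch logs a routing warning but the detected class wins, so a shifted or
corrupted page fails loudly instead of feeding a tomogram to OCR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .layout_config import FieldKind, FieldSpec, crop_region
from .value_reader import _otsu

__all__ = ["ContentClass", "RoutedRegion", "route_region", "detect_content_class"]

logger = logging.getLogger("octreport.area_explorer")


class ContentClass:
    NUMERIC_TEXT = "numeric_text"
    TOMOGRAM = "tomogram"
    EMPTY = "empty"


#: Which content class each configured field kind should produce.
_EXPECTED = {
    FieldKind.NUMERIC: ContentClass.NUMERIC_TEXT,
    FieldKind.DATE: ContentClass.NUMERIC_TEXT,
    FieldKind.TEXT: ContentClass.NUMERIC_TEXT,
    FieldKind.TOMOGRAM: ContentClass.TOMOGRAM,
}


@dataclass(frozen=True)
class RoutedRegion:
    field: FieldSpec
    content_class: str
    crop: np.ndarray


def detect_content_class(crop: np.ndarray, ink_epsilon: float = 0.005,
                         tomogram_fill: float = 0.20) -> str:
    """Classify a crop as numeric text, tomogram, or empty.

    Text is sparse ink on a plain background (small minority-class fraction
    after Otsu binarization); tomograms are dense grayscale with a large
    foreground fraction; anything with less ink than ``ink_epsilon`` is empty.
    """
    arr = np.asarray(crop)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float32)
    if float(arr.max() - arr.min()) < 25.0:
        return ContentClass.EMPTY
    mask = arr < _otsu(arr)
    frac = float(mask.mean())
    fill = min(frac, 1.0 - frac)  # minority-class fraction
    if fill < ink_epsilon:
        return ContentClass.EMPTY
    if fill > tomogram_fill:
        return ContentClass.TOMOGRAM
    return ContentClass.NUMERIC_TEXT


def route_region(page: np.ndarray, field: FieldSpec,
                 ink_epsilon: float = 0.005, tomogram_fill: float = 0.20,
                 page_path: str = "") -> RoutedRegion:
    """Crop a field's box and decide where its content belongs.

    Never mutates the page; the returned crop equals
    ``crop_region(page, field.box)`` pixel for pixel.
    """
    crop = crop_region(page, field.box)
    detected = detect_content_class(crop, ink_epsilon, tomogram_fill)
    expected = _EXPECTED[field.kind]
    if detected != ContentClass.EMPTY and detected != expected:
        logger.warning(
            "field %r on %s: configured kind %r but detected %s; honoring detection",
            field.name, page_path or "<page>", field.kind, detected)
    return RoutedRegion(field=field, content_class=detected, crop=crop)
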