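"""Identify a report page's layout type from its header region.

Each layout paints a distinct title at a known header box.  Classification
crops each candidate header box, binarizes it, and compares it against the
layout's rendered title template by zero-mean normalized correlation — a
deterministic, training-free test that works before any recognizer exists.
If no template clears the acceptance threshold, a text match through the
reference recognizer is tried as a fallback; failing both, the page is
rejected as an unknown report type.

Binarization plus normalized correlation makes the decision invariant to
global brightness/contrast changes of the page.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .layout_config import LayoutCatalog, ReportLayout, crop_region
from .value_reader import RecognitionFailure, ReferenceRecognizer, _otsu

__all__ = ["ClassificationResult", "UnknownReportType", "classify_report",
           "header_score"]


class UnknownReportType(RuntimeError):
    """No layout's header title matched the page above threshold."""


@dataclass(frozen=True)
class ClassificationResult:
    type_id: str
    score: float  # similarity in [0, 1]
    header_text: str


@lru_cache(maxsize=64)
def _binary_template(type_id: str, header_title: str, box: tuple,
                     page_size: tuple) -> np.ndarray:
    # cache key mirrors everything the template depends on
    from .synthetic import render_title_template

    tpl = render_title_template(_TemplateProxy(type_id, header_title, box, page_size))
    return tpl < 128


class _TemplateProxy:
    """Light stand-in carrying just the attributes the renderer needs."""

    def __init__(self, type_id, header_title, header_box, page_size):
        self.type_id = type_id
        self.header_title = header_title
        self.header_box = header_box
        self.page_size = page_size


def _binarize(crop: np.ndarray) -> np.ndarray | None:
    arr = np.asarray(crop)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float32)
    if float(arr.max() - arr.min()) < 25.0:
        return None  # featureless region
    return arr < _otsu(arr)


def header_score(image: np.ndarray, layout: ReportLayout) -> float:
    """Similarity in [0,1] between the page's header crop and the layout title."""
    crop = crop_region(image, layout.header_box)
    mask = _binarize(crop)
    if mask is None:
        return 0.0
    tpl = _binary_template(layout.type_id, layout.header_title,
                           tuple(layout.header_box), tuple(layout.page_size))
    a = mask.astype(np.float32) - mask.mean()
    b = tpl.astype(np.float32) - tpl.mean()
    denom = float(np.sqrt((a * a).sum() * (b * b).sum()))
    if denom < 1e-9:
        return 0.0
    return max(0.0, float((a * b).sum() / denom))


def classify_report(image: np.ndarray, catalog: LayoutCatalog) -> ClassificationResult:
    """Pick the layout whose header title best matches the page.

    Ties break toward the lexicographically lowest ``type_id`` and the result
    is independent of catalog order.  Raises :class:`UnknownReportType` when
    nothing clears ``classifier.accept_threshold``.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    threshold = float(catalog.setting("classifier.accept_threshold"))
    candidates = [l for l in sorted(catalog.layouts, key=lambda l: l.type_id)
                  if l.header_box[2] <= w and l.header_box[3] <= h]
    if not candidates:
        raise UnknownReportType(
            f"image {w}x{h} is smaller than every layout's header region")
    best_layout, best_score = None, -1.0
    for layout in candidates:
        score = header_score(arr, layout)
        if score > best_score:
            best_layout, best_score = layout, score
    if best_score >= threshold:
        return ClassificationResult(best_layout.type_id, best_score,
                                    best_layout.header_title)
    # fallback: read the header text and compare against canonical titles
    reader = ReferenceRecognizer(catalog.charset)
    for layout in candidates:
        try:
            rec = reader.recognize(crop_region(arr, layout.header_box))
        except RecognitionFailure:
            continue
        if rec.text.strip().upper() == layout.header_title.upper():
            return ClassificationResult(layout.type_id, max(best_score, rec.confidence),
                                        rec.text.strip())
    raise UnknownReportType(
        f"no header title matched above threshold {threshold} "
        f"(best score {best_score:.3f})")
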