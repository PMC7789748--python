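"""Score extraction output against ground truth, per report category.

A report counts as a success only when every non-missing truth field matches
the predicted raw text exactly (string equality) — the same all-or-nothing
criterion a human checker applies when verifying a whole report.  Rates are
reported per validated category and pooled overall (pooled counts, never a
mean of rates).  Only the three numeric report categories are validated;
unilateral and bilateral RNFL reports share one category because they are
read by the identical algorithm.  Scan-only types carry no characters and are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import ExtractedRecord
from .synthetic import SyntheticReport

__all__ = [
    "VALIDATION_CATEGORIES",
    "AccuracyReport",
    "score_extraction",
    "sample_validation_set",
    "category_of",
]

#: category name -> type_ids pooled into it
VALIDATION_CATEGORIES: dict[str, tuple[str, ...]] = {
    "rnfl": ("rnfl_unilateral", "rnfl_bilateral"),
    "macula_current": ("macula_current",),
    "macula_prev_current": ("macula_prev_current",),
}


def category_of(type_id: str) -> str | None:
    for cat, tids in VALIDATION_CATEGORIES.items():
        if type_id in tids:
            return cat
    return None


@dataclass(frozen=True)
class AccuracyReport:
    n_reports: dict[str, int]        # per category + "total"
    n_success: dict[str, int]
    field_tallies: dict[str, tuple[int, int]]  # field name -> (n_correct, n)

    def success_rate(self, key: str = "total") -> float:
        n = self.n_reports[key]
        return round(100.0 * self.n_success[key] / n, 2) if n else float("nan")

    def failure_rate(self, key: str = "total") -> float:
        n = self.n_reports[key]
        return round(100.0 - self.success_rate(key), 2) if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        cols = ["total"] + [c for c in self.n_reports if c != "total"]
        data = {
            "Number of reports": [self.n_reports[c] for c in cols],
            "Success (%)": [self.success_rate(c) for c in cols],
            "Failure (%)": [self.failure_rate(c) for c in cols],
        }
        return pd.DataFrame(data, index=[("Total" if c == "total" else c) for c in cols]).T


def reconstruct_raw_texts(record: ExtractedRecord, catalog) -> dict[str, str]:
    """Rebuild per-field raw texts from a CSV-parsed record.

    Measurement columns carry canonical (eye-stripped) names; map them back
    to the layout's on-page field names for this record's eye, and add the
    page-metadata fields.  Used by the CLI validate path, where predictions
    arrive as CSV rather than in-memory records.
    """
    layout = catalog[record.type_id]
    raw: dict[str, str] = {}
    for m in record.measurements:
        for f in layout.numeric_fields:
            from .pipeline import canonical_field_name

            if canonical_field_name(f.name) == m.name and \
                    f.eye in (None, record.laterality):
                raw[f.name] = m.raw_text
    for f in layout.fields:
        if f.name == "patient_id":
            raw[f.name] = record.patient_id
        elif f.kind == "date":
            raw[f.name] = record.visit_date
        elif f.name == "laterality" and record.laterality:
            raw[f.name] = record.laterality.upper()
    return raw


def _records_by_source(predictions: list[ExtractedRecord]) -> dict[str, list[ExtractedRecord]]:
    by_src: dict[str, list[ExtractedRecord]] = {}
    for rec in predictions:
        by_src.setdefault(rec.source_path, []).append(rec)
    return by_src


def score_extraction(predictions: list[ExtractedRecord],
                     truths: dict[str, dict]) -> AccuracyReport:
    """Tally report-level successes against sidecar truth.

    ``truths`` maps source path -> sidecar dict (``type_id`` plus a ``truth``
    mapping of field name -> painted string).  Bilateral reports produce two
    prediction records per source; their raw texts are merged before
    comparison.  Raises on any prediction/truth mismatch in the keying.
    """
    by_src = _records_by_source(predictions)
    missing = sorted(set(by_src) ^ set(truths))
    if missing:
        raise ValueError(f"unmatched prediction/truth source paths: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    n_reports: dict[str, int] = {"total": 0}
    n_success: dict[str, int] = {"total": 0}
    field_tallies: dict[str, list[int]] = {}
    for src, sidecar in truths.items():
        cat = category_of(sidecar["type_id"])
        if cat is None:
            continue  # scan-only types carry no characters to validate
        raw: dict[str, str] = {}
        for rec in by_src[src]:
            raw.update(rec.raw_texts)
        ok = True
        for name, expected in sidecar["truth"].items():
            if expected in ("", None):
                continue
            match = raw.get(name, "") == expected
            tally = field_tallies.setdefault(name, [0, 0])
            tally[0] += int(match)
            tally[1] += 1
            ok = ok and match
        for key in (cat, "total"):
            n_reports[key] = n_reports.get(key, 0) + 1
            n_success[key] = n_success.get(key, 0) + int(ok)
        if cat not in n_reports:
            n_reports[cat] = 0
            n_success[cat] = 0
    return AccuracyReport(
        n_reports=n_reports, n_success=n_success,
        field_tallies={k: (v[0], v[1]) for k, v in field_tallies.items()})


def sample_validation_set(fixtures: list[SyntheticReport], n_per_category: int,
                          seed: int = 0) -> list[SyntheticReport]:
    """Draw a reproducible validation subset, n per validated category."""
    rng = np.random.default_rng(seed)
    chosen: list[SyntheticReport] = []
    for cat, tids in VALIDATION_CATEGORIES.items():
        pool = [f for f in fixtures if f.type_id in tids]
        if len(pool) < n_per_category:
            raise ValueError(
                f"insufficient fixtures for category {cat!r}: "
                f"{len(pool)} available, {n_per_category} requested")
        idx = rng.choice(len(pool), size=n_per_category, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen
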