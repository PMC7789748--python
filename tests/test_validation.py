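"""Accuracy scoring against sidecar truth, per report category."""

import pytest

import octreport as oc
from octreport.pipeline import ExtractedRecord
from octreport.validation import (
    VALIDATION_CATEGORIES,
    sample_validation_set,
    score_extraction,
)


def _make_pair(src, type_id, truth, predicted=None):
    predicted = truth if predicted is None else predicted
    rec = ExtractedRecord(patient_id="1", visit_date="2020-01-01",
                          type_id=type_id, laterality="right", measurements=[],
                          source_path=src, raw_texts=dict(predicted))
    sidecar = {"type_id": type_id, "truth": dict(truth)}
    return rec, sidecar


def _population(n_per_cat, fail_in=None):
    """n reports per category; optionally one wrong field in one category."""
    preds, truths = [], {}
    tids = {"rnfl": "rnfl_unilateral", "macula_current": "macula_current",
            "macula_prev_current": "macula_prev_current"}
    for cat, tid in tids.items():
        for i in range(n_per_cat):
            src = f"{cat}_{i}.png"
            truth = {"central_value": str(300 + i), "patient_id": "12349876"}
            predicted = dict(truth)
            if fail_in == cat and i == 0:
                predicted["central_value"] = "999"
            rec, sidecar = _make_pair(src, tid, truth, predicted)
            preds.append(rec)
            truths[src] = sidecar
    return preds, truths


def test_299_of_300_gives_the_9967_overall_rate():
    preds, truths = _population(100, fail_in="macula_current")
    report = score_extraction(preds, truths)
    assert report.n_reports["total"] == 300
    assert report.n_success["total"] == 299
    assert report.success_rate("total") == 99.67
    assert report.failure_rate("total") == 0.33
    assert report.success_rate("rnfl") == 100.0
    assert report.success_rate("macula_current") == 99.0
    assert report.success_rate("macula_prev_current") == 100.0


def test_perfect_predictions_score_100_everywhere():
    preds, truths = _population(20)
    report = score_extraction(preds, truths)
    for key in report.n_reports:
        assert report.success_rate(key) == 100.0
        assert report.failure_rate(key) == 0.0


def test_success_plus_failure_is_100_per_column():
    preds, truths = _population(30, fail_in="rnfl")
    report = score_extraction(preds, truths)
    for key in report.n_reports:
        assert report.success_rate(key) + report.failure_rate(key) == \
            pytest.approx(100.0)


def test_overall_is_pooled_counts_not_mean_of_rates():
    # unbalanced categories: pooled rate differs from the mean of rates
    preds, truths = _population(10, fail_in="rnfl")
    extra, extruths = _population(40)
    for rec in extra:
        rec.source_path = "x_" + rec.source_path
    preds += [r for r in extra if r.type_id == "macula_current"]
    truths.update({"x_" + k: v for k, v in extruths.items()
                   if v["type_id"] == "macula_current"})
    report = score_extraction(preds, truths)
    pooled = 100.0 * report.n_success["total"] / report.n_reports["total"]
    assert report.success_rate("total") == round(pooled, 2)
    rates = [report.success_rate(c) for c in VALIDATION_CATEGORIES]
    assert report.success_rate("total") != round(sum(rates) / len(rates), 2)


def test_scoring_is_order_insensitive_and_idempotent():
    preds, truths = _population(15, fail_in="macula_prev_current")
    a = score_extraction(preds, truths)
    b = score_extraction(list(reversed(preds)), truths)
    c = score_extraction(preds, truths)
    assert a == b == c


def test_unmatched_sources_rejected():
    preds, truths = _population(3)
    truths["orphan.png"] = {"type_id": "macula_current", "truth": {}}
    with pytest.raises(ValueError, match="unmatched"):
        score_extraction(preds, truths)


def test_scan_only_types_are_excluded_from_scoring():
    preds, truths = _population(5)
    rec, sidecar = _make_pair("scan.png", "macula_scan_current", {})
    preds.append(rec)
    truths["scan.png"] = sidecar
    report = score_extraction(preds, truths)
    assert report.n_reports["total"] == 15


def test_sampling_is_reproducible_and_sized(catalog):
    fixtures = oc.generate_reports(catalog, n_per_type=5, seed=7)
    subset = sample_validation_set(fixtures, n_per_category=5, seed=1)
    assert len(subset) == 15  # 3 validated categories
    again = sample_validation_set(fixtures, n_per_category=5, seed=1)
    assert [r.patient_id for r in subset] == [r.patient_id for r in again]
    with pytest.raises(ValueError, match="insufficient"):
        sample_validation_set(fixtures, n_per_category=50, seed=1)
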