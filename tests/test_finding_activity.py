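"""Finding classification on phantoms and the longitudinal activity rule."""

import math

import numpy as np
import pytest

from octreport.finding_activity import (
    ActivityLabel,
    VisitObservation,
    classify_finding,
    derive_activity,
)
from octreport.synthetic import render_tomogram_phantom, synth_text_image

SRF = "subretinal_fluid"


def _series(points):
    """points: list of (date, cmt, srf_present)"""
    return [VisitObservation(d, c, {SRF: f}) for d, c, f in points]


# ---------------------------------------------------------------------------
# activity rule

def test_first_visit_is_always_not_applicable():
    labels = derive_activity(_series([("2013-07-17", 364.0, True)]))
    assert labels == [ActivityLabel.NOT_APPLICABLE]


def test_large_cmt_drop_is_improvement():
    labels = derive_activity(_series([("2013-07-17", 364.0, True),
                                      ("2013-08-27", 251.0, True)]))
    assert labels[1] == ActivityLabel.IMPROVEMENT  # -31% < -threshold


def test_small_drop_with_fluid_resolution_is_stationary():
    labels = derive_activity(_series([("2013-08-27", 251.0, True),
                                      ("2013-10-10", 218.0, False)]))
    assert labels[1] == ActivityLabel.STATIONARY  # -13%; resolution alone != improvement


def test_new_finding_or_large_rise_is_worsening():
    up = derive_activity(_series([("2020-01-01", 200.0, False),
                                  ("2020-02-01", 260.0, False)]))
    assert up[1] == ActivityLabel.WORSENING  # +30%
    new = derive_activity(_series([("2020-01-01", 200.0, False),
                                   ("2020-02-01", 205.0, True)]))
    assert new[1] == ActivityLabel.WORSENING  # fluid newly appeared


def test_label_depends_only_on_adjacent_visits():
    pts = [("2019-01-01", 400.0, True), ("2019-02-01", 260.0, True),
           ("2019-03-01", 250.0, False), ("2019-04-01", 330.0, False),
           ("2019-05-01", 320.0, True)]
    full = derive_activity(_series(pts))
    for k in range(1, len(pts)):
        pair = derive_activity(_series(pts[k - 1:k + 1]))
        assert pair[1] == full[k]


def test_infinite_threshold_yields_stationary_without_new_findings():
    pts = [("2019-01-01", 400.0, False), ("2019-02-01", 100.0, False),
           ("2019-03-01", 900.0, False)]
    labels = derive_activity(_series(pts), threshold=math.inf)
    assert labels == [ActivityLabel.NOT_APPLICABLE, ActivityLabel.STATIONARY,
                      ActivityLabel.STATIONARY]


def test_unsorted_series_rejected_and_missing_cmt_skipped(caplog):
    with pytest.raises(ValueError, match="sorted"):
        derive_activity(_series([("2020-02-01", 1.0, False),
                                 ("2020-01-01", 1.0, False)]))
    with caplog.at_level("WARNING", logger="octreport.finding_activity"):
        labels = derive_activity(_series([("2020-01-01", 200.0, False),
                                          ("2020-02-01", None, False),
                                          ("2020-03-01", 210.0, False)]))
    assert labels[1] is None and labels[2] is None
    assert any("missing CMT" in m for m in caplog.messages)


def test_nonpositive_threshold_rejected():
    with pytest.raises(ValueError):
        derive_activity(_series([("2020-01-01", 1.0, False)]), threshold=0.0)


# ---------------------------------------------------------------------------
# baseline finding classifier

def test_classifier_separates_findings_on_held_out_phantoms(finding_model):
    rng = np.random.default_rng(404)
    correct = {name: 0 for name in finding_model.vocabulary}
    n = 60
    crops, flags = [], []
    for _ in range(n):
        f = {name: bool(rng.random() < 0.5) for name in finding_model.vocabulary}
        crops.append(render_tomogram_phantom(f, int(rng.integers(0, 2**31 - 1))))
        flags.append(f)
    results = finding_model.predict_batch(crops)
    for fr, f in zip(results, flags):
        for name in finding_model.vocabulary:
            correct[name] += (fr.labels[name] == f[name])
    for name, c in correct.items():
        assert c / n >= 0.9, (name, c / n)


def test_classifier_is_deterministic_at_inference(finding_model):
    crop = render_tomogram_phantom({SRF: True}, seed=8)
    a = finding_model.predict(crop)
    b = finding_model.predict(crop)
    assert a.probabilities == b.probabilities


def test_present_iff_probability_at_least_half(finding_model):
    crop = render_tomogram_phantom({SRF: True, "macular_edema": False}, seed=9)
    fr = finding_model.predict(crop)
    for name, p in fr.probabilities.items():
        assert fr.labels[name] == (p >= 0.5)


def test_text_crop_rejected_as_non_tomogram(finding_model):
    crop = synth_text_image("364", seed=1).image
    with pytest.raises(ValueError, match="tomogram"):
        classify_finding(crop, finding_model)
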