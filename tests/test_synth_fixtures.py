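"""The synthetic data source: corpora, phantoms, report pages, sidecars."""

import numpy as np
import pytest
from skimage.measure import label, regionprops

from octreport.layout_config import crop_region
from octreport.synthetic import (
    CLEAN_STYLE,
    CorpusSpec,
    MIN_BLOB_AREA,
    TextStyle,
    generate_corpus,
    load_sidecar,
    render_report,
    render_tomogram_phantom,
    sample_label,
    sample_report,
    save_report,
    synth_text_image,
)


# ---------------------------------------------------------------------------
# text images

def test_clean_render_is_deterministic():
    a = synth_text_image("364", CLEAN_STYLE, seed=5)
    b = synth_text_image("364", CLEAN_STYLE, seed=5)
    assert np.array_equal(a.image, b.image)
    noisy = TextStyle(noise=10.0)
    c = synth_text_image("364", noisy, seed=5)
    d = synth_text_image("364", noisy, seed=5)
    assert np.array_equal(c.image, d.image)
    e = synth_text_image("364", noisy, seed=6)
    assert not np.array_equal(c.image, e.image)


@pytest.mark.parametrize("bad,err", [
    ("", "empty"),
    ("x" * 51, "longer than 50"),
    ("héllo", "outside charset"),
])
def test_invalid_labels_rejected(bad, err):
    with pytest.raises(ValueError, match=err):
        synth_text_image(bad)


def test_reference_readout_matches_label_on_clean_styles(catalog, reference):
    """Generator/recognizer agreement on a 1,000-label random sample."""
    rng = np.random.default_rng(99)
    mismatches = []
    for i in range(1000):
        lab = sample_label(rng, catalog.charset)
        style = TextStyle(font=("sans", "mono")[i % 2],
                          size=int(rng.integers(14, 29)))
        s = synth_text_image(lab, style, seed=i, charset=catalog.charset)
        rec = reference.recognize(s.image)
        if rec.text != lab:
            mismatches.append((lab, rec.text, style))
    assert not mismatches, mismatches[:5]


# ---------------------------------------------------------------------------
# corpora

def test_split_sizes_follow_the_092_008_convention():
    spec = CorpusSpec(n_total=1000, seed=0)
    train, val = generate_corpus(spec)
    assert (len(train), len(val)) == (920, 80)


@pytest.mark.parametrize("n_total,frac", [(250, 0.92), (1000, 0.75), (37, 0.5)])
def test_split_arithmetic_is_exact(n_total, frac):
    train, val = generate_corpus(CorpusSpec(n_total=n_total, train_fraction=frac,
                                            seed=1))
    assert len(train) == round(n_total * frac)
    assert len(train) + len(val) == n_total


def test_corpus_reproducible_from_seed():
    spec = CorpusSpec(n_total=60, seed=7)
    t1, v1 = generate_corpus(spec)
    t2, v2 = generate_corpus(spec)
    assert [s.label for s in t1] == [s.label for s in t2]
    for a, b in zip(t1[:10] + v1[:5], t2[:10] + v2[:5]):
        assert np.array_equal(a.image, b.image)


def test_digit_restricted_corpus_stays_within_charset():
    train, val = generate_corpus(CorpusSpec(n_total=100, seed=3,
                                            charset="0123456789"))
    for s in train + val:
        assert s.label and set(s.label) <= set("0123456789")


def test_degenerate_corpus_spec_rejected():
    with pytest.raises(ValueError):
        CorpusSpec(n_total=1)
    with pytest.raises(ValueError):
        CorpusSpec(n_total=10, train_fraction=1.0)


# ---------------------------------------------------------------------------
# tomogram phantoms

def test_phantom_negative_control_has_no_large_dark_blob():
    img = render_tomogram_phantom({"subretinal_fluid": False,
                                   "macular_edema": False}, seed=11)
    h = img.shape[0]
    interior = img[int(0.40 * h):int(0.74 * h), :]
    dark = label(interior < 50)
    areas = [r.area for r in regionprops(dark)]
    assert not areas or max(areas) < MIN_BLOB_AREA


def test_subretinal_fluid_paints_connected_dark_blob():
    for seed in (1, 2, 3):
        img = render_tomogram_phantom({"subretinal_fluid": True}, seed=seed)
        h = img.shape[0]
        interior = img[int(0.36 * h):int(0.76 * h), :]
        dark = label(interior < 50)
        areas = [r.area for r in regionprops(dark)]
        assert areas and max(areas) >= MIN_BLOB_AREA


def test_phantom_determinism_and_unknown_finding():
    a = render_tomogram_phantom({"macular_edema": True}, seed=4)
    b = render_tomogram_phantom({"macular_edema": True}, seed=4)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError, match="unknown finding"):
        render_tomogram_phantom({"drusen": True}, seed=0)


# ---------------------------------------------------------------------------
# report pages

def test_rendered_page_matches_layout_size_and_truth_fields(catalog):
    for tid in catalog.type_ids:
        rep = sample_report(catalog[tid], seed=5)
        w, h = catalog[tid].page_size
        assert rep.image.shape == (h, w)
        expected = {f.name for f in catalog[tid].fields if f.kind != "tomogram"}
        assert set(rep.truth) == expected


def test_truth_layout_mismatch_rejected(catalog):
    layout = catalog["macula_current"]
    with pytest.raises(ValueError, match="mismatch"):
        render_report({"total_macular_volume": "9.08"}, layout,
                      patient_id="1", visit_date="2020-01-01", laterality="right")


def test_sidecar_consistency_crops_read_back_exactly(catalog, reference):
    """Cropping each field box and reading it reproduces the sidecar truth."""
    for tid in ("macula_current", "rnfl_bilateral"):
        layout = catalog[tid]
        rep = sample_report(layout, seed=77)
        for f in layout.fields:
            if f.kind == "tomogram":
                continue
            crop = crop_region(rep.image, f.box)
            assert reference.recognize(crop).text == rep.truth[f.name]


def test_missing_value_renders_as_dash_placeholder(catalog, reference):
    layout = catalog["macula_current"]
    values = {"patient_id": "12349876", "visit_date": "2013-07-17",
              "laterality": "RIGHT", "total_macular_volume": "--",
              "central_macular_thickness": "364"}
    rep = render_report(values, layout, patient_id="12349876",
                        visit_date="2013-07-17", laterality="right")
    crop = crop_region(rep.image, layout.field("total_macular_volume").box)
    assert reference.recognize(crop).text == "--"


def test_save_report_sidecar_round_trip(catalog, tmp_path):
    rep = sample_report(catalog["macula_current"], seed=9)
    img_path, json_path = save_report(rep, tmp_path, "r0")
    sidecar = load_sidecar(json_path)
    assert sidecar["truth"] == rep.truth
    assert sidecar["type_id"] == rep.type_id
    assert sidecar["laterality"] == rep.laterality
    from PIL import Image
    assert np.array_equal(np.asarray(Image.open(img_path)), rep.image)
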