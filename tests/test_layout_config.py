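"""Catalog schema validation, serialization round trips, and cropping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octreport.layout_config import (
    CatalogError,
    FieldSpec,
    SCAN_ONLY_TYPES,
    catalog_from_dict,
    catalog_to_dict,
    crop_region,
    load_catalog,
    save_catalog,
)


def test_default_catalog_has_six_distinct_layouts(catalog):
    assert len(catalog.layouts) == 6
    titles = [l.header_title for l in catalog.layouts]
    assert len(set(titles)) == 6
    assert catalog.is_complete


def test_every_bundled_box_lies_inside_its_page(catalog):
    for layout in catalog.layouts:
        w, h = layout.page_size
        for f in (*layout.fields,):
            x0, y0, x1, y1 = f.box
            assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h


def test_scan_only_layouts_carry_no_numeric_fields(catalog):
    for tid in SCAN_ONLY_TYPES:
        layout = catalog[tid]
        assert not layout.numeric_fields
        assert layout.tomogram_fields


def test_catalog_serialization_round_trip(catalog, tmp_path):
    p = tmp_path / "cat.yaml"
    save_catalog(catalog, p)
    again = load_catalog(p)
    assert again == catalog
    assert again.charset == catalog.charset


def test_degenerate_box_rejected_naming_field():
    with pytest.raises(CatalogError, match="bad_field"):
        FieldSpec(name="bad_field", kind="numeric", box=(50, 50, 40, 60))


def test_duplicate_header_titles_rejected(catalog):
    doc = catalog_to_dict(catalog)
    doc["layouts"][1]["header_title"] = doc["layouts"][0]["header_title"]
    with pytest.raises(CatalogError, match="duplicate header titles"):
        catalog_from_dict(doc)


def test_box_outside_page_rejected_naming_layout(catalog):
    doc = catalog_to_dict(catalog)
    doc["layouts"][0]["fields"][0]["box"] = [0, 0, 9999, 20]
    with pytest.raises(CatalogError, match="rnfl_unilateral"):
        catalog_from_dict(doc)


def test_missing_file_and_bad_yaml(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_catalog(tmp_path / "nope.yaml")
    p = tmp_path / "bad.yaml"
    p.write_text("{not: [valid")
    with pytest.raises(CatalogError):
        load_catalog(p)


def test_crop_region_copies_expected_pixels(rng):
    img = rng.integers(0, 256, size=(10, 10), dtype=np.uint8)
    crop = crop_region(img, (0, 0, 5, 5))
    assert crop.shape == (5, 5)
    assert np.array_equal(crop, img[:5, :5])
    assert np.array_equal(crop_region(img, (0, 0, 10, 10)), img)
    with pytest.raises(ValueError):
        crop_region(img, (2, 2, 11, 5))


@given(x0=st.integers(0, 30), y0=st.integers(0, 20),
       w=st.integers(1, 10), h=st.integers(1, 10))
def test_crop_reembed_round_trip_is_lossless(x0, y0, w, h):
    rng = np.random.default_rng(x0 * 1000 + y0 * 50 + w * 10 + h)
    img = rng.integers(0, 256, size=(32, 42), dtype=np.uint8)
    box = (x0, y0, min(x0 + w, 42), min(y0 + h, 32))
    before = img.copy()
    crop = crop_region(img, box)
    assert np.array_equal(img, before), "source must not be modified"
    assert crop.shape == (box[3] - box[1], box[2] - box[0])
    rebuilt = img.copy()
    rebuilt[box[1]:box[3], box[0]:box[2]] = crop
    assert np.array_equal(rebuilt, img)
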