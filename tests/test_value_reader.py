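"""Recognition backends, training behavior, and value parsing."""

import numpy as np
import pytest

from octreport.layout_config import FieldSpec
from octreport.synthetic import CorpusSpec, TextStyle, generate_corpus, synth_text_image
from octreport.value_reader import (
    MAX_DECODE_LEN,
    Measurement,
    OcrModel,
    ParseError,
    Recognition,
    RecognitionFailure,
    TrainConfig,
    load_model,
    normalize_crop,
    parse_value,
    recognize,
    save_model,
    train,
)


# ---------------------------------------------------------------------------
# reference recognizer

@pytest.mark.parametrize("text", ["9.08", "189", "364", "8.21"])
def test_reference_reads_clean_values_exactly(reference, text):
    s = synth_text_image(text, seed=2)
    rec = reference.recognize(s.image)
    assert rec.text == text
    assert rec.confidence > 0.8


def test_reference_fails_loudly_on_heavy_noise(reference):
    s = synth_text_image("364", TextStyle(noise=80.0), seed=3)
    with pytest.raises(RecognitionFailure):
        reference.recognize(s.image)


def test_reference_returns_empty_for_blank_crop(reference):
    blank = np.full((30, 80), 255, dtype=np.uint8)
    assert reference.recognize(blank).text == ""


# ---------------------------------------------------------------------------
# parsing

def _numeric_field(pattern=None, unit="µm"):
    return FieldSpec(name="central_macular_thickness", kind="numeric",
                     box=(0, 0, 10, 10), unit=unit, pattern=pattern)


def test_parse_value_returns_typed_measurement():
    m = parse_value(Recognition("364", 0.99), _numeric_field())
    assert m == Measurement("central_macular_thickness", 364.0, "µm", "364")
    assert not m.is_missing


@pytest.mark.parametrize("dash", ["--", "-"])
def test_dash_placeholder_is_missing_not_zero(dash):
    m = parse_value(Recognition(dash, 0.9), _numeric_field())
    assert m.is_missing
    assert m.value is None


@pytest.mark.parametrize("bad", ["3..6", "36a", "", "9.0.8"])
def test_malformed_text_raises_parse_error_with_raw_text(bad):
    with pytest.raises(ParseError) as exc:
        parse_value(Recognition(bad, 0.9), _numeric_field())
    assert exc.value.raw_text == bad


def test_pattern_from_field_spec_is_enforced():
    field = _numeric_field(pattern=r"\d+\.\d{2}", unit="mm³")
    assert parse_value(Recognition("9.08", 1.0), field).value == 9.08
    with pytest.raises(ParseError):
        parse_value(Recognition("9.0", 1.0), field)


def test_parse_value_rejects_non_numeric_fields():
    f = FieldSpec(name="laterality", kind="text", box=(0, 0, 5, 5))
    with pytest.raises(ValueError, match="numeric"):
        parse_value(Recognition("RIGHT", 1.0), f)


def test_format_parse_round_trip_at_printed_precision(reference):
    for v in ("9.08", "8.21", "8.05", "364", "251", "189"):
        s = synth_text_image(v, seed=4)
        rec = reference.recognize(s.image)
        m = parse_value(rec, _numeric_field())
        assert f"{m.value:.2f}".rstrip("0").rstrip(".") == v or m.raw_text == v


# ---------------------------------------------------------------------------
# trainable model

def test_train_config_invariants():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(iterations=0)


def test_tiny_training_run_decreases_loss():
    charset = "0123456789."
    tr, va = generate_corpus(CorpusSpec(n_total=500, seed=10, charset=charset,
                                        max_len=5))
    cfg = TrainConfig(iterations=250, eval_every=125, val_subset=40, seed=2,
                      hidden=24, attn_dim=16, embed_dim=12)
    model, curves = train(tr, va, cfg, charset=charset)
    assert curves[-1]["loss"] < curves[0]["loss"]
    assert all({"iteration", "loss", "val_accuracy"} <= set(c) for c in curves)


def test_training_rejects_bad_inputs():
    tr, va = generate_corpus(CorpusSpec(n_total=20, seed=1))
    with pytest.raises(ValueError, match="non-empty"):
        train([], va, TrainConfig(iterations=1))
    with pytest.raises(ValueError, match="charset"):
        train(tr, va, TrainConfig(iterations=1), charset="01")


def test_decoder_never_exceeds_fifty_characters():
    model = OcrModel(charset="01", hidden=8, attn_dim=8, embed_dim=4, seed=0)
    wide = synth_text_image("10" * 25, seed=1, charset="01 ").image
    rec = model.recognize(wide)
    assert len(rec.text) <= MAX_DECODE_LEN


def test_untrained_model_on_blank_crop_is_rejected_low_confidence():
    model = OcrModel(charset="01", hidden=8, attn_dim=8, embed_dim=4, seed=0)
    rec = model.recognize(np.full((30, 60), 255, dtype=np.uint8))
    assert rec.text == ""
    assert rec.confidence < 0.5


def test_recognize_rejects_empty_array():
    model = OcrModel(charset="01", hidden=8, attn_dim=8, embed_dim=4, seed=0)
    with pytest.raises(ValueError):
        recognize(model, np.zeros((0, 0)))


def test_normalize_crop_is_invariant_to_background_padding():
    s = synth_text_image("425", seed=6)
    base = normalize_crop(s.image)
    padded = np.pad(s.image, 4, constant_values=255)
    assert np.array_equal(normalize_crop(padded), base)


def test_checkpoint_save_load_round_trip(tmp_path):
    charset = "0123456789."
    tr, va = generate_corpus(CorpusSpec(n_total=80, seed=5, charset=charset,
                                        max_len=4))
    cfg = TrainConfig(iterations=20, eval_every=20, val_subset=10, seed=3,
                      hidden=16, attn_dim=8, embed_dim=8)
    model, _ = train(tr, va, cfg, charset=charset)
    path = tmp_path / "ocr.npz"
    save_model(model, path)
    again = load_model(path)
    crop = va[0].image
    assert again.recognize(crop) == model.recognize(crop)


# ---------------------------------------------------------------------------
# desk-scale trained model (session checkpoint)

def test_trained_model_reads_clean_values(trained_model):
    for text in ("9.08", "364", "2013-07-17", "RIGHT"):
        s = synth_text_image(text, TextStyle(size=17), seed=8)
        assert trained_model.recognize(s.image).text == text


def test_trained_model_tolerates_small_padding(trained_model):
    s = synth_text_image("8.21", TextStyle(size=17), seed=9)
    base = trained_model.recognize(s.image).text
    padded = np.pad(s.image, 4, constant_values=255)
    assert trained_model.recognize(padded).text == base == "8.21"


def test_validation_accuracy_envelope_is_non_decreasing(trained_model):
    env = np.maximum.accumulate([c["val_accuracy"] for c in trained_model.curves])
    assert list(env) == sorted(env)


def test_trained_model_matches_reference_on_clean_crops(trained_model, reference,
                                                        catalog):
    """Oracle equivalence on clean numeric crops after desk-scale training."""
    rng = np.random.default_rng(17)
    agree = total = 0
    for i in range(300):
        kind = rng.choice(["int", "dec"])
        text = (f"{rng.integers(40, 600)}" if kind == "int"
                else f"{rng.uniform(5, 13):.2f}")
        s = synth_text_image(text, TextStyle(size=int(rng.integers(15, 22))),
                             seed=1000 + i, charset=catalog.charset)
        total += 1
        agree += (trained_model.recognize(s.image).text
                  == reference.recognize(s.image).text)
    assert agree / total >= 0.99


# ---------------------------------------------------------------------------
# pattern-constrained decoding

@pytest.mark.parametrize("pattern,expected", [
    (r"\d{2,3}", "0123456789"),
    (r"\d+\.\d{2}", "0123456789."),
    (r"RIGHT|LEFT", "EFGHILRT"),
    (r"[A-C]-\d", "0123456789-ABC"),
    (None, None),
    (r".*", None),
])
def test_allowed_chars_derived_from_field_patterns(pattern, expected):
    from octreport.layout_config import DEFAULT_CHARSET
    from octreport.value_reader import allowed_chars_from_pattern

    assert allowed_chars_from_pattern(pattern, DEFAULT_CHARSET) == expected


def test_constrained_decode_never_emits_disallowed_characters():
    model = OcrModel(charset="01AB", hidden=8, attn_dim=8, embed_dim=4, seed=3)
    crop = synth_text_image("01A", seed=2, charset="01AB").image
    rec = model.recognize(crop, allowed="01")
    assert set(rec.text) <= {"0", "1"}


def test_reference_recognizer_honors_allowed_alphabet(reference):
    s = synth_text_image("405", seed=11)
    assert reference.recognize(s.image, allowed="0123456789").text == "405"
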