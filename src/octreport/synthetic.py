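"""Synthetic data: OCR training corpora, tomogram phantoms, mock report pages.

Real device reports cannot be redistributed, so this module is the package's
only data source.  It emulates three things:

* **Text-image corpora** for training the recognizer: strings drawn from the
  catalog charset (integers, decimals, dates, uppercase tokens) rendered at
  varying font, size, contrast, background texture and Gaussian noise.
* **Tomogram phantoms**: layered horizontal bands mimicking retinal strata,
  with optional pathology (a dark sub-band blob for subretinal fluid, a
  central bump plus cystic spaces for macular edema).
* **Full report pages**: a header title plus every configured field painted
  inside its catalog box, returned together with a ground-truth sidecar that
  downstream tests use as the extraction oracle.

Glyphs come from bundled open-license DejaVu fonts.  Text is laid out glyph
by glyph with a fixed inter-glyph gap, so segmentation-based template
matching (the deterministic reference recognizer) can read clean renders
exactly.  Everything is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .layout_config import (
    DEFAULT_CHARSET,
    FieldKind,
    LayoutCatalog,
    ReportLayout,
)

__all__ = [
    "TextStyle",
    "TextSample",
    "CorpusSpec",
    "SyntheticReport",
    "CLEAN_STYLE",
    "REPORT_STYLE",
    "TITLE_STYLE",
    "MAX_LABEL_LEN",
    "FONT_IDS",
    "render_text",
    "synth_text_image",
    "sample_label",
    "generate_corpus",
    "render_tomogram_phantom",
    "render_report",
    "sample_report",
    "generate_reports",
    "save_report",
    "load_sidecar",
    "MIN_BLOB_AREA",
]

MAX_LABEL_LEN = 50

#: Minimum pixel area of the subretinal-fluid blob painted by the phantom.
MIN_BLOB_AREA = 120


# ---------------------------------------------------------------------------
# fonts

def _font_paths() -> dict[str, str]:
    import matplotlib

    ttf = Path(matplotlib.get_data_path()) / "fonts" / "ttf"
    return {
        "sans": str(ttf / "DejaVuSans.ttf"),
        "mono": str(ttf / "DejaVuSansMono.ttf"),
    }


_FONT_PATHS = _font_paths()
FONT_IDS = tuple(sorted(_FONT_PATHS))
_FONT_CACHE: dict[tuple[str, int], ImageFont.FreeTypeFont] = {}


def _font(font_id: str, size: int) -> ImageFont.FreeTypeFont:
    key = (font_id, size)
    if key not in _FONT_CACHE:
        if font_id not in _FONT_PATHS:
            raise ValueError(f"unknown font id {font_id!r}; have {FONT_IDS}")
        _FONT_CACHE[key] = ImageFont.truetype(_FONT_PATHS[font_id], size)
    return _FONT_CACHE[key]


# ---------------------------------------------------------------------------
# text rendering

@dataclass(frozen=True)
class TextStyle:
    """Rendering style: font, size, contrast in (0,1], noise sigma, background id.

    ``contrast`` sets the ink level (1.0 = black on white); ``noise`` is the
    standard deviation of additive Gaussian pixel noise in gray levels;
    ``background`` selects texture strength (0 none, 1 light, 2 medium).
    """

    font: str = "sans"
    size: int = 18
    contrast: float = 1.0
    noise: float = 0.0
    background: int = 0

    def __post_init__(self):
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


CLEAN_STYLE = TextStyle()
#: Style used when painting values onto synthetic report pages.
REPORT_STYLE = TextStyle(font="sans", size=17)
TITLE_STYLE = TextStyle(font="sans", size=20)


@dataclass
class TextSample:
    image: np.ndarray  # uint8 grayscale
    label: str
    style: TextStyle


def _glyph_gap(size: int) -> int:
    return max(2, size // 8)


def _space_advance(size: int) -> int:
    return max(7, int(round(0.75 * size)))


_INK_CACHE: dict[tuple[str, int, str], tuple[int, int]] = {}


def _ink_extent(font_id: str, size: int, ch: str) -> tuple[int, int]:
    """(left offset, width) of a glyph's binarized ink columns.

    Measured on an isolated render so glyph placement uses the same ink
    boundaries that binarization sees — inter-glyph gaps come out uniform.
    """
    key = (font_id, size, ch)
    if key not in _INK_CACHE:
        font = _font(font_id, size)
        l, _, r, _ = font.getbbox(ch)
        if r <= l:
            raise ValueError(f"font {font_id!r} has no glyph for {ch!r}")
        ascent, descent = font.getmetrics()
        probe = Image.new("L", (r - l + 8, ascent + descent + 4), 255)
        ImageDraw.Draw(probe).text((4 - l, 2), ch, font=font, fill=0)
        cols = (np.asarray(probe) < 128).any(axis=0)
        if cols.any():
            idx = np.nonzero(cols)[0]
            _INK_CACHE[key] = (int(idx[0]) - 4 + l, int(idx[-1] - idx[0] + 1))
        else:  # glyph too faint to binarize; fall back to the bbox
            _INK_CACHE[key] = (l, r - l)
    return _INK_CACHE[key]


def render_text(text: str, style: TextStyle = CLEAN_STYLE, pad: int = 3) -> np.ndarray:
    """Render a string to a grayscale uint8 array, black-on-white, no noise.

    Glyphs are placed by binarized ink width with a fixed gap (no kerning),
    which keeps adjacent glyphs separable for template matching.
    Noise/contrast live in :func:`synth_text_image`; this returns the clean
    bitmap.
    """
    if text == "":
        raise ValueError("refusing to render an empty label")
    font = _font(style.font, style.size)
    ascent, descent = font.getmetrics()
    gap = _glyph_gap(style.size)
    # first pass: positions
    placements: list[tuple[str, int, int]] = []  # (char, ink_x, ink_left)
    x = pad
    for ch in text:
        if ch == " ":
            x += _space_advance(style.size)
            continue
        ink_left, ink_w = _ink_extent(style.font, style.size, ch)
        placements.append((ch, x, ink_left))
        x += ink_w + gap
    width = max(x - gap + pad, 2 * pad + 1) if placements else x + pad
    height = ascent + descent + 2 * pad
    img = Image.new("L", (width, height), 255)
    draw = ImageDraw.Draw(img)
    for ch, px, ink_left in placements:
        draw.text((px - ink_left, pad), ch, font=font, fill=0)
    return np.asarray(img, dtype=np.uint8)


def _apply_style(clean: np.ndarray, style: TextStyle, rng: np.random.Generator) -> np.ndarray:
    out = clean.astype(np.float32)
    fg = 255.0 * (1.0 - style.contrast)
    # remap ink range [0,255] -> [fg, 255]
    out = fg + out * (255.0 - fg) / 255.0
    if style.background > 0:
        h, w = out.shape
        amp = 12.0 * style.background
        gy = np.linspace(0, 2 * np.pi * rng.uniform(0.5, 2.0), h)
        gx = np.linspace(0, 2 * np.pi * rng.uniform(0.5, 2.0), w)
        texture = np.sin(gy + rng.uniform(0, 2 * np.pi))[:, None] * \
            np.cos(gx + rng.uniform(0, 2 * np.pi))[None, :]
        out = out - amp * (texture + 1.0) / 2.0
    if style.noise > 0:
        out = out + rng.normal(0.0, style.noise, out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def synth_text_image(label: str, style: TextStyle = CLEAN_STYLE,
                     seed: int = 0, charset: str = DEFAULT_CHARSET) -> TextSample:
    """Render one labeled text image; deterministic given (label, style, seed)."""
    if label == "":
        raise ValueError("empty labels are rejected; missing values render as '--'")
    if len(label) > MAX_LABEL_LEN:
        raise ValueError(f"label longer than {MAX_LABEL_LEN} characters: {len(label)}")
    bad = sorted(set(label) - set(charset))
    if bad:
        raise ValueError(f"label contains characters outside charset: {bad}")
    rng = np.random.default_rng(seed)
    clean = render_text(label, style)
    return TextSample(image=_apply_style(clean, style, rng), label=label, style=style)


# ---------------------------------------------------------------------------
# corpus generation

@dataclass(frozen=True)
class CorpusSpec:
    """What to generate for recognizer training.

    The split fraction follows the convention of holding out 8% of the
    corpus for validation.  ``style_ranges`` bounds the random styles:
    ``size`` (pt), ``contrast``, ``noise`` (gray levels), and background
    texture ids with probabilities.
    """

    n_total: int
    train_fraction: float = 0.92
    seed: int = 0
    charset: str = DEFAULT_CHARSET
    max_len: int = 10
    style_ranges: dict = field(default_factory=lambda: {
        "size": (14, 28),
        "contrast": (0.6, 1.0),
        "noise": (0.0, 18.0),
        "background_p": (0.5, 0.3, 0.2),
    })

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (1 <= self.max_len <= MAX_LABEL_LEN):
            raise ValueError(f"max_len must be in [1, {MAX_LABEL_LEN}]")


_WORDS = ("RIGHT", "LEFT", "OD", "OS", "OU", "NA")


def sample_label(rng: np.random.Generator, charset: str = DEFAULT_CHARSET,
                 max_len: int = 12) -> str:
    """Draw one label shaped like report-page content (numbers, dates, tokens)."""
    digits = [c for c in "0123456789" if c in charset]
    letters = [c for c in charset if c.isalpha()]
    if not digits:
        n = rng.integers(1, max_len + 1)
        return "".join(rng.choice(list(charset.replace(" ", "") or charset), n))
    # mix mirrors the field kinds a report page carries (one id, one date,
    # one laterality word, several numerics) plus robustness fillers
    kind = rng.choice(
        ["int", "decimal", "date", "id", "signed", "percent", "word", "mixed"],
        p=[0.22, 0.18, 0.15, 0.15, 0.04, 0.03, 0.15, 0.08])
    if kind == "id" and max_len < 9:
        kind = "int"
    if kind == "decimal" and "." not in charset:
        kind = "int"
    if kind == "date" and ("-" not in charset or max_len < 10):
        kind = "int"
    if kind == "signed" and "-" not in charset:
        kind = "int"
    if kind == "percent" and "%" not in charset:
        kind = "int"
    if kind in ("word", "mixed") and not letters:
        kind = "int"

    if kind == "int":
        n = int(rng.integers(1, min(5, max_len) + 1))
        s = "".join(rng.choice(digits, n))
    elif kind == "id":
        # identifier-style long digit runs (patient ids and the like)
        n = int(rng.integers(6, 10))
        s = "".join(rng.choice(digits, n))
    elif kind == "decimal":
        a = int(rng.integers(1, 4))
        b = int(rng.integers(1, 3))
        s = "".join(rng.choice(digits, a)) + "." + "".join(rng.choice(digits, b))
    elif kind == "date":
        y = int(rng.integers(2006, 2020))
        m = int(rng.integers(1, 13))
        d = int(rng.integers(1, 29))
        s = f"{y:04d}-{m:02d}-{d:02d}"
    elif kind == "signed":
        s = "-" + "".join(rng.choice(digits, int(rng.integers(1, 4))))
    elif kind == "percent":
        s = "".join(rng.choice(digits, int(rng.integers(1, 3)))) + "%"
    elif kind == "word":
        if rng.random() < 0.5:
            s = str(rng.choice(_WORDS))
        else:
            s = "".join(rng.choice(letters, int(rng.integers(2, 9))))
        s = "".join(c for c in s if c in charset) or "".join(rng.choice(digits, 3))
    else:  # mixed
        n = int(rng.integers(3, 9))
        pool = letters + digits
        s = "".join(rng.choice(pool, n))
    return s[:max_len]


def _sample_style(rng: np.random.Generator, ranges: dict) -> TextStyle:
    lo, hi = ranges["size"]
    clo, chi = ranges["contrast"]
    nlo, nhi = ranges["noise"]
    bg_p = np.asarray(ranges["background_p"], dtype=float)
    bg_p = bg_p / bg_p.sum()
    return TextStyle(
        font=str(rng.choice(FONT_IDS)),
        size=int(rng.integers(lo, hi + 1)),
        contrast=float(rng.uniform(clo, chi)),
        noise=float(rng.uniform(nlo, nhi)),
        background=int(rng.choice(len(bg_p), p=bg_p)),
    )


def generate_corpus(spec: CorpusSpec) -> tuple[list[TextSample], list[TextSample]]:
    """Generate (train, validation) text-image sets, reproducible from seed.

    |train| = round(n_total * train_fraction); the remainder is validation.
    """
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.n_total * spec.train_fraction))
    n_train = min(max(n_train, 1), spec.n_total - 1)
    samples: list[TextSample] = []
    for _ in range(spec.n_total):
        label = sample_label(rng, spec.charset, spec.max_len)
        style = _sample_style(rng, spec.style_ranges)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        samples.append(synth_text_image(label, style, sub_seed, spec.charset))
    return samples[:n_train], samples[n_train:]


# ---------------------------------------------------------------------------
# tomogram phantoms

_FINDING_NAMES = ("subretinal_fluid", "macular_edema")


def render_tomogram_phantom(finding_flags: dict[str, bool], seed: int = 0,
                            size: tuple[int, int] = (440, 170)) -> np.ndarray:
    """Render a layered-band retinal phantom, optionally with pathology.

    The phantom mimics a B-scan's gross appearance: a bright inner band, a
    medium stroma, and a bright outer (RPE-like) band over a dark vitreous/
    choroid background.  ``subretinal_fluid`` paints a dark hypo-intense blob
    between the stroma and the outer band; ``macular_edema`` bulges the inner
    band centrally and adds small cystic voids.  Deterministic given seed.
    """
    unknown = sorted(set(finding_flags) - set(_FINDING_NAMES))
    if unknown:
        raise ValueError(f"unknown finding names: {unknown}; expected {_FINDING_NAMES}")
    w, h = size
    rng = np.random.default_rng(seed)
    img = np.full((h, w), 16.0, dtype=np.float32)
    xx = np.arange(w, dtype=np.float32)
    yy = np.arange(h, dtype=np.float32)[:, None]

    phase = rng.uniform(0, 2 * np.pi)
    curve = 0.05 * h * np.sin(2 * np.pi * xx / w + phase)
    top = 0.30 * h + curve
    if finding_flags.get("macular_edema", False):
        cx = rng.uniform(0.35, 0.65) * w
        sigma = 0.12 * w
        top = top - 0.14 * h * np.exp(-((xx - cx) / sigma) ** 2)
    rpe = 0.78 * h + 0.3 * curve
    t_top = max(3, int(0.05 * h))
    t_rpe = max(3, int(0.04 * h))

    img[(yy >= top) & (yy < top + t_top)] = 190.0
    img[(yy >= top + t_top) & (yy < rpe)] = 90.0
    img[(yy >= rpe) & (yy < rpe + t_rpe)] = 205.0
    img[yy >= rpe + t_rpe] = 38.0

    if finding_flags.get("subretinal_fluid", False):
        cx = rng.uniform(0.30, 0.70) * w
        cy = float(np.mean(top + t_top + (rpe - top - t_top) * 0.6))
        a = rng.uniform(0.09, 0.15) * w
        b = rng.uniform(0.09, 0.14) * h
        # guarantee the blob clears the configured minimum area
        min_ab = MIN_BLOB_AREA / np.pi * 1.5
        if a * b < min_ab:
            scale = np.sqrt(min_ab / (a * b))
            a, b = a * scale, b * scale
        blob = ((xx[None, :] - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        img[blob & (yy > top + t_top) & (yy < rpe)] = 22.0

    if finding_flags.get("macular_edema", False):
        n_cysts = int(rng.integers(2, 5))
        for _ in range(n_cysts):
            ccx = rng.uniform(0.25, 0.75) * w
            ccy = float(np.mean(top + t_top)) + rng.uniform(0.15, 0.5) * (
                float(np.mean(rpe)) - float(np.mean(top + t_top)))
            r = max(2.5, rng.uniform(0.025, 0.05) * h)
            cyst = ((xx[None, :] - ccx)) ** 2 + ((yy - ccy)) ** 2 <= r ** 2
            img[cyst & (yy > top + t_top) & (yy < rpe)] = 45.0

    img += rng.normal(0.0, 4.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# full report pages

@dataclass
class SyntheticReport:
    """A rendered report page plus its machine-readable ground truth."""

    image: np.ndarray
    truth: dict[str, str]  # field name -> painted string (non-tomogram fields)
    type_id: str
    patient_id: str
    visit_date: str
    laterality: str | None  # None for bilateral layouts (both eyes on page)
    finding_flags: dict[str, bool]
    source_path: str = ""


def _fit_text(text: str, box_w: int, box_h: int, style: TextStyle) -> np.ndarray:
    size = style.size
    while size >= 7:
        bmp = render_text(text, TextStyle(style.font, size, 1.0, 0.0, 0), pad=2)
        if bmp.shape[1] <= box_w - 2 and bmp.shape[0] <= box_h - 2:
            return bmp
        size -= 1
    raise ValueError(f"text {text!r} cannot fit a {box_w}x{box_h} box")


def paint_text_in_box(page: np.ndarray, box, text: str, style: TextStyle) -> None:
    """Paint text centered inside a box (in place); glyphs never cross the box."""
    x0, y0, x1, y1 = box
    bmp = _fit_text(text, x1 - x0, y1 - y0, style)
    bh, bw = bmp.shape
    ox = x0 + ((x1 - x0) - bw) // 2
    oy = y0 + ((y1 - y0) - bh) // 2
    region = page[oy:oy + bh, ox:ox + bw]
    np.minimum(region, bmp, out=region)


def render_title_template(layout: ReportLayout) -> np.ndarray:
    """The header region exactly as the renderer paints it (classifier template)."""
    x0, y0, x1, y1 = layout.header_box
    tpl = np.full((y1 - y0, x1 - x0), 255, dtype=np.uint8)
    paint_text_in_box(tpl, (0, 0, x1 - x0, y1 - y0), layout.header_title, TITLE_STYLE)
    return tpl


def render_report(values: dict[str, str], layout: ReportLayout, *,
                  patient_id: str, visit_date: str, laterality: str | None,
                  finding_flags: dict[str, bool] | None = None,
                  style: TextStyle = REPORT_STYLE, seed: int = 0) -> SyntheticReport:
    """Paint truth values onto a blank page following the layout.

    ``values`` must cover exactly the layout's non-tomogram fields (missing
    optional values are passed as the dash placeholder ``"--"``).  Tomogram
    fields are filled with phantoms driven by ``finding_flags``.
    """
    finding_flags = dict(finding_flags or {})
    expected = {f.name for f in layout.fields if f.kind != FieldKind.TOMOGRAM}
    got = set(values)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"truth/layout field mismatch for {layout.type_id}: "
            f"missing={missing} extra={extra}")

    w, h = layout.page_size
    page = np.full((h, w), 255, dtype=np.uint8)
    paint_text_in_box(page, layout.header_box, layout.header_title, TITLE_STYLE)
    rule_y = min(layout.header_box[3] + 4, h - 1)
    page[rule_y, layout.header_box[0]:layout.header_box[2]] = 120

    rng = np.random.default_rng(seed)
    for f in layout.fields:
        if f.kind == FieldKind.TOMOGRAM:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            phantom = render_tomogram_phantom(
                finding_flags, seed=sub_seed, size=(f.width, f.height))
            page[f.box[1]:f.box[3], f.box[0]:f.box[2]] = phantom
        else:
            paint_text_in_box(page, f.box, values[f.name], style)

    if style.noise > 0 or style.background > 0 or style.contrast < 1.0:
        page = _apply_style(page, style, rng)

    return SyntheticReport(
        image=page, truth=dict(values), type_id=layout.type_id,
        patient_id=patient_id, visit_date=visit_date, laterality=laterality,
        finding_flags=finding_flags)


def _format_value(field_name: str, unit: str, rng: np.random.Generator) -> str:
    name = field_name.lower()
    if "volume" in name or unit == "mm3" or unit == "mm³":
        return f"{rng.uniform(5.5, 12.5):.2f}"
    if "rnfl" in name:
        return str(int(rng.integers(40, 141)))
    if "thickness" in name or unit in ("µm", "um", "μm"):
        return str(int(rng.integers(150, 601)))
    return str(int(rng.integers(0, 1000)))


def sample_report(layout: ReportLayout, seed: int = 0,
                  style: TextStyle = REPORT_STYLE,
                  patient_id: str | None = None) -> SyntheticReport:
    """Draw a random but internally consistent report for a layout."""
    rng = np.random.default_rng(seed)
    pid = patient_id or f"{rng.integers(10_000_000, 100_000_000)}"
    y = int(rng.integers(2006, 2020))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    visit_date = f"{y:04d}-{m:02d}-{d:02d}"
    bilateral = any(f.eye for f in layout.fields)
    laterality = None if bilateral else str(rng.choice(["right", "left"]))
    finding_flags = {
        "subretinal_fluid": bool(rng.random() < 0.35),
        "macular_edema": bool(rng.random() < 0.25),
    }
    values: dict[str, str] = {}
    for f in layout.fields:
        if f.kind == FieldKind.TOMOGRAM:
            continue
        if f.kind == FieldKind.DATE:
            values[f.name] = visit_date
        elif f.kind == FieldKind.TEXT:
            if f.name == "patient_id":
                values[f.name] = pid
            elif f.name == "laterality":
                values[f.name] = {"right": "RIGHT", "left": "LEFT"}[laterality]
            else:
                values[f.name] = str(rng.choice(_WORDS))
        else:
            values[f.name] = _format_value(f.name, f.unit, rng)
    render_seed = int(rng.integers(0, 2**31 - 1))
    return render_report(values, layout, patient_id=pid, visit_date=visit_date,
                         laterality=laterality, finding_flags=finding_flags,
                         style=style, seed=render_seed)


def generate_reports(catalog: LayoutCatalog, n_per_type: int, seed: int = 0,
                     style: TextStyle = REPORT_STYLE,
                     type_ids: tuple[str, ...] | None = None) -> list[SyntheticReport]:
    rng = np.random.default_rng(seed)
    out: list[SyntheticReport] = []
    for tid in (type_ids or catalog.type_ids):
        layout = catalog[tid]
        for _ in range(n_per_type):
            out.append(sample_report(layout, int(rng.integers(0, 2**31 - 1)), style))
    return out


# ---------------------------------------------------------------------------
# sidecars

def save_report(report: SyntheticReport, out_dir, stem: str) -> tuple[Path, Path]:
    """Write the page as PNG and the truth sidecar as JSON (same basename)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.png"
    json_path = out_dir / f"{stem}.json"
    Image.fromarray(report.image).save(img_path)
    sidecar = {
        "type_id": report.type_id,
        "patient_id": report.patient_id,
        "visit_date": report.visit_date,
        "laterality": report.laterality,
        "finding_flags": report.finding_flags,
        "truth": report.truth,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return img_path, json_path


def load_sidecar(json_path) -> dict:
    return json.loads(Path(json_path).read_text())
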