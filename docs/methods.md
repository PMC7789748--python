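# Methods

`octreport` converts raster OCT report pages into structured, longitudinal
measurement records. This note documents the models and procedures it
implements, the choices made where the design was genuinely open, and what
the synthetic test bed does and does not demonstrate.

## Pipeline

A page flows through five stages:

1. **Report classification.** Each of the six supported layouts paints a
   distinct title in a known header box. The classifier crops each candidate
   header box, binarizes it at the midpoint of the crop's intensity range
   (which makes the decision invariant to global brightness/contrast
   scaling), and computes the zero-mean normalized correlation against the
   layout's rendered title template. The best score wins if it clears
   `classifier.accept_threshold` (default 0.7); ties break toward the
   lexicographically lowest `type_id`, so the result is independent of
   catalog order. If no template clears the threshold, the header text is
   read with the reference recognizer and compared against the canonical
   titles; failing both, the page is rejected as an unknown report type.
   Both a pixel path and a text path are provided because either is a
   plausible reading of "classify by the header" on real devices.
2. **Region routing.** Every configured field box is cropped and classified
   by content: after binarization, a minority-class pixel fraction below
   `area_explorer.ink_epsilon` (0.5%) means *empty*; above
   `area_explorer.tomogram_fill` (20%) means *tomogram* (dense grayscale);
   anything between is *numeric text* (sparse ink on a plain background).
   The detected class is cross-checked against the configured field kind; on
   disagreement a warning is logged and the detected class wins, so a
   shifted or corrupted page fails loudly instead of feeding a tomogram to
   OCR. The thresholds are calibrated together with the synthetic renderer;
   the routing property test (200 random fixtures, 100% agreement) verifies
   exactly that calibration, not performance on arbitrary scans.
3. **Value reading.** Text crops go to one of two recognizer backends
   (below); recognized strings are validated against the field's regular
   expression and parsed into unit-bearing measurements. A read that
   violates the field's declared shape (wrong digit count, impossible
   structure) is deterministically re-attempted on rescaled views of the
   crop (1.5x, 0.75x, 2x) and the first conforming result wins — recognizer
   mistakes are brittle to resampling, so a second view usually recovers
   the true string; if none conforms the original read stands and downstream
   parsing records the failure as a warning. The dash placeholder (`--` or
   `-`) parses to an explicit missing value, never zero. Dates are
   normalized to ISO-8601 using the catalog's configured on-page format.
4. **Finding classification.** Tomogram crops go to a pluggable finding
   model; the bundled baseline is a small convolutional network trained on
   rendered phantoms. With several panels on one page, per-finding
   probabilities are combined by maximum (disease present if any panel
   shows it).
5. **Assembly and output.** Bilateral layouts emit one record per eye
   (per-eye fields are tagged in the catalog and their shared canonical name
   keeps both eyes in one CSV column). Records are grouped per
   (patient, laterality), sorted by visit date, labeled with disease
   activity, and written as CSV, OMOP-CDM MEASUREMENT-shaped rows, and
   losslessly exported tomogram crops.

## The trainable recognizer

The Value Reader follows the standard three-stage scene-text recognition
design: a convolutional feature extractor (three 3x3 convolution blocks with
a residual connection; the first two stages pool 2x2, the last pools height
only, so a height-32 input collapses to a left-to-right feature sequence at
1/4 horizontal resolution — roughly four steps per glyph), a bidirectional
LSTM sequence model (48 hidden units per direction), and a location-aware
additive-attention decoder (LSTM state 48, greedy decoding) that emits
characters recurrently until end-of-sequence or the 50-character cap.  The
alignment score sees the previous step's attention weights and their running
sum alongside the encoder features and decoder state; without that location
feedback, purely content-based attention drops or duplicates characters in
long runs of visually identical glyphs (eight-digit patient identifiers were
the failure mode that motivated it). Training uses teacher forcing with masked cross-entropy, AdaDelta
(learning rate 1, decay 0.95), batch size 32, and gradient-norm clipping
at 5. The checkpoint returned is the one with the best validation sequence
accuracy.

The network and its training loop are implemented on a compact reverse-mode
automatic-differentiation engine written on numpy (`octreport/_nn.py`);
gradient correctness is pinned by tests against loop-computed references and
numeric differentiation.

Input crops are normalized by tight-cropping to the ink bounding box
(with a 2 px margin), resizing to height 32 with preserved aspect ratio, and
per-image intensity standardization; batches pad to a common width on a
32-px grid, at training and inference alike (a mismatch between the two
padding grids measurably degrades end-of-sequence behavior). Tight-cropping
first makes recognition invariant to background padding around the region.

Confidence is the geometric mean of the decoded characters' probabilities
(length-normalized, comparable across fields); recognitions below 0.5 are
treated as unreliable.

Decoding is **pattern-constrained**: each catalog field declares its
expected character class (a restricted regular expression — digits for
thickness values, digits plus a decimal point for volumes, the laterality
words, and so on), and the decoder masks characters outside that class
(end-of-sequence always stays available; numeric fields additionally admit
the dash placeholder; date fields admit digits plus the date format's
literal separators). This is the OCR analogue of lexicon-constrained
decoding: it removes the near-twin substitutions a field can never contain
(reading the digit zero as the letter O was the dominant residual error) and
applies identically to the trained model and the template-matching reference
backend. Fields without a declared pattern decode unconstrained.

Training additionally maintains Polyak-averaged shadow weights
(exponential moving average, decay 0.999); at every evaluation point both
the raw and the averaged weights are scored on the validation split and the
overall best checkpoint is returned, which smooths the late-training
fluctuation AdaDelta exhibits at a fixed learning rate of 1.

### Training conditions

The synthetic corpus draws labels shaped like report content — integers,
fixed-point decimals, ISO dates, long identifier digit runs, uppercase
tokens (including laterality words), percents and mixed alphanumerics —
rendered in two bundled DejaVu fonts at 14–28 pt, contrast 0.6–1.0, additive
Gaussian noise up to sigma 18, and optional low-frequency background
texture. Label lengths are capped at 10 characters, the longest string a
report page carries (an ISO date). The split convention holds out 8% for
validation. Desk-scale defaults are a 20,000-sample corpus and 11,000
iterations (about a quarter hour on one CPU core); both are plain
configuration values, so full-scale runs (about one million samples,
160,000 iterations) use the same code path.

## The deterministic reference recognizer

Pipeline plumbing is verified independently of training by a
template-matching recognizer that shares glyph shapes with the synthetic
renderer. It segments the binarized crop into glyph runs by column gaps,
estimates the rendering size from the tallest run's ink height, and jointly
selects the (font, size) whose templates best explain *all* runs under
zero-mean mask correlation (maximized over one-pixel shifts, because tight
boxes of different width parity otherwise misalign thin strokes). Near-tie
scores resolve toward digits, reflecting the predominantly numeric content.
Spaces are inserted at gaps that are large both on the glyph-height scale
and relative to the crop's median inter-glyph gap. A glyph whose best score
falls below tolerance (0.55) raises a recognition failure — heavy noise
fails loudly rather than silently. The renderer places glyphs by binarized
ink extent with a fixed gap precisely so that this segmentation is exact on
clean renders; the generator and the oracle are two halves of one test
instrument.

## Tomogram phantoms and the baseline finding model

Phantoms mimic a B-scan's gross geometry: a bright inner band, a medium
stroma, a bright outer band over a dark background, with sinusoidal
curvature and Gaussian pixel noise. Subretinal fluid adds a dark elliptical
blob between stroma and outer band (guaranteed to exceed the 120 px minimum
area); macular edema bulges the inner band centrally and adds small cystic
voids. The baseline classifier is a two-conv-block network with one two-way
softmax head per finding, trained on 240 random phantoms for 300 AdaDelta
iterations. It exists to make the pipeline end-to-end testable and to fix
the plug-in interface; it says nothing about real B-scans, and clinical
finding detection is explicitly out of scope.

## Disease activity

Activity labels compare consecutive visits of one (patient, laterality)
series: the first visit is *not applicable*; later visits are *improvement*
when central macular thickness (CMT) falls by at least the threshold
fraction θ, *worsening* when CMT rises by at least θ or a finding newly
appears, and *stationary* otherwise. A finding that merely resolves does not
by itself constitute improvement, and each label depends only on the
adjacent pair of visits. The published example course constrains θ to
(0.206, 0.310]: the −31% drop must label improvement while −13.1%, +8.3%,
+0.8% and −20.6% changes must all label stationary. The default θ = 0.25 is
the midpoint of that interval; it is exposed as `activity.threshold`.

## Validation protocol

A report counts as a success only when every non-missing ground-truth field
matches the predicted raw text exactly — an all-or-nothing, report-level
criterion. Rates are reported per category at two decimals, with the overall
rate computed from pooled counts (never a mean of per-category rates).
Three categories are validated — RNFL (unilateral and bilateral pooled,
since both are read by the identical algorithm), macula current-only, and
macula previous-and-current; scan-only layouts carry no characters and are
excluded. The accuracy benchmark extracts 300 clean synthetic reports
(100 per category) with the desk-trained recognizer.

## What the synthetic test bed does not show

Synthetic pages are rendered with the same fonts, glyph metrics and layout
boxes the recognizers are built around; real Spectralis pages differ in
font, rasterization, compression artifacts and scan geometry. Passing the
synthetic benchmarks demonstrates that the pipeline is lossless, the
training loop converges, and the whole system meets the reported accuracy
bar *under the emulated conditions* — not that the bundled catalog or
trained checkpoint transfer to real devices. Adapting to a real device
means editing the layout catalog (coordinates, titles, date format) and
retraining on a corpus styled after that device's rendering.

## Numerical and degenerate-input choices

* Coordinates are 0-based, half-open rectangles; widths are exact
  subtractions.
* Empty labels are rejected by the text renderer; missing report values are
  painted as the dash placeholder instead.
* An all-background crop recognizes as an empty string with zero confidence;
  empty regions under numeric fields become explicit missing measurements
  with a warning.
* Classifier ties break lexicographically; the decoder is greedy (no beam
  search), keeping inference deterministic given weights.
* All randomness flows through `numpy.random.default_rng` seeds; corpus
  generation, phantom rendering, training and sampling are reproducible
  bit-for-bit from their seeds.
* Visits with a missing CMT (or missing predecessor CMT) get no activity
  label and a warning, never a silently imputed one.

## Known limitations

* Page skew, rotation and multi-page documents are out of scope; crops are
  taken at configured coordinates only.
* The reference recognizer assumes near-native rendering scale; heavily
  rescaled input falls back to scale-normalized matching, which is weaker.
* The finding baseline saturates on phantoms and is not a clinical model.
* CDM output stops at MEASUREMENT-shaped rows with placeholder concept ids;
  site ETL and PACS/DICOM transfer are integration work, not library code.
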