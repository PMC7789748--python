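# octreport

Structured, longitudinal measurements from ophthalmic (OCT) report images.

Retinal OCT devices print their results — macular volume, central macular
thickness, RNFL thickness, tomographic panels — onto fixed-layout report
pages that are archived as plain raster images. Locked inside pixels, those
measurements cannot be trended over visits, loaded into a research database,
or audited at scale. `octreport` is a toolkit for clinical-informatics teams
that turns such pages back into typed, unit-bearing, per-patient/per-eye
records:

* a **layout catalog** (hand-editable YAML) that says where every value and
  tomogram lives on each of six supported report layouts;
* a **report classifier** that identifies the layout from the page header
  (normalized template correlation, text match as fallback);
* an **area explorer** that routes each configured region to OCR, to the
  finding classifier, or flags it empty;
* a **value reader** with two backends: a trainable three-stage scene-text
  recognizer (convolutional feature extraction → bidirectional LSTM →
  attention decoder, trained with AdaDelta on synthetic corpora) and a
  deterministic template-matching reference recognizer used as the plumbing
  oracle;
* a **finding classifier** interface (with a phantom-trained convolutional
  baseline) and a **disease-activity rule** over consecutive visits of one
  eye: improvement when central macular thickness falls by ≥ θ (default
  0.25), worsening when it rises by ≥ θ or a finding newly appears,
  stationary otherwise;
* **output writers** for longitudinal CSV, OMOP-CDM MEASUREMENT-shaped rows,
  and lossless tomogram crop export;
* a **synthetic data module** that renders mock report pages with
  ground-truth sidecars, OCR training corpora, and tomogram phantoms — the
  package's only data source, and the oracle its tests are built on.

Everything is plain numpy/Pillow/pandas; the recognizer and its training
loop run on a small reverse-mode autodiff engine included in the package.

## Worked example

Extract a rendered six-visit course of a treated eye and derive activity:

```python
import octreport as oc
from octreport import pipeline

catalog = oc.default_catalog()
layout = catalog["macula_current"]

visits = [("2013-07-17", "9.08", "364", True),
          ("2013-08-27", "8.21", "251", True),
          ("2013-10-10", "8.16", "218", False)]

records = []
for date, tmv, cmt, srf in visits:
    page = oc.render_report(
        {"patient_id": "12349876", "visit_date": date, "laterality": "RIGHT",
         "total_macular_volume": tmv, "central_macular_thickness": cmt},
        layout, patient_id="12349876", visit_date=date, laterality="right",
        finding_flags={"subretinal_fluid": srf}, seed=7)
    rec = pipeline.process_image(page.image, catalog)[0]  # reference OCR
    rec.findings = oc.FindingResult.from_probabilities(
        {"subretinal_fluid": float(srf)})
    records.append(rec)

pipeline.assign_activity(records, catalog=catalog)
for r in records:
    m = r.measurement
    print(r.visit_date, r.laterality,
          m("total_macular_volume").value, m("central_macular_thickness").value,
          r.findings.labels["subretinal_fluid"], r.activity)
```

prints

```
2013-07-17 right 9.08 364.0 True not_applicable
2013-08-27 right 8.21 251.0 True improvement
2013-10-10 right 8.16 218.0 False stationary
```

— the first visit has no predecessor, the −31% thickness drop labels the
second visit an improvement, and the −13% change at the third is
stationary even though the fluid resolved (resolution alone is not
improvement). `pipeline.write_csv(records, "out.csv", catalog)` writes the
same course as one sorted longitudinal table;
`pipeline.to_cdm_rows(records, pipeline.default_concept_map())` yields one
MEASUREMENT-shaped row per value (e.g. 9.08 mm³, 364 µm).

## Command line

```bash
octreport generate --kind reports --n 10 --seed 1 --out pages/
octreport train-ocr --corpus 20000 --iterations 11000 --seed 1 --out ocr.npz
octreport extract --in pages/ --model ocr.npz --out results.csv \
                  --cdm-out cdm.csv --crops-out crops/
octreport validate --pred results.csv --truth pages/ --out accuracy.csv
```

`extract --reference-ocr` swaps in the deterministic template matcher.

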