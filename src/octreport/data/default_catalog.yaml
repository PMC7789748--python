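# Default layout catalog for the synthetic report renderer.
#
# Coordinates are 0-based half-open pixel rectangles [x0, y0, x1, y1]
# (x rightward, y downward). Real-device catalogs are supplied the same way:
# edit the boxes, keep the schema.
charset: "0123456789.-%/: ABCDEFGHIJKLMNOPQRSTUVWXYZ"
settings:
  classifier:
    accept_threshold: 0.7
  area_explorer:
    ink_epsilon: 0.005
    tomogram_fill: 0.20
  activity:
    threshold: 0.25
  findings:
    vocabulary: [subretinal_fluid, macular_edema]
  date_format: "%Y-%m-%d"
layouts:
  - type_id: rnfl_unilateral
    header_title: "RNFL SINGLE EXAM REPORT"
    header_box: [16, 12, 390, 46]
    page_size: [560, 420]
    version_range: "1.7.0.0-1.10.4.0"
    fields:
      - {name: patient_id, kind: text, box: [402, 14, 552, 40], pattern: "\\d{8}"}
      - {name: visit_date, kind: date, box: [402, 44, 552, 70]}
      - {name: laterality, kind: text, box: [24, 60, 150, 86], pattern: "RIGHT|LEFT"}
      - {name: avg_rnfl_thickness, kind: numeric, box: [180, 120, 310, 152],
         unit: "µm", pattern: "\\d{2,3}"}
      - {name: superior_rnfl_thickness, kind: numeric, box: [180, 170, 310, 202],
         unit: "µm", pattern: "\\d{2,3}"}
      - {name: inferior_rnfl_thickness, kind: numeric, box: [180, 220, 310, 252],
         unit: "µm", pattern: "\\d{2,3}"}
  - type_id: rnfl_bilateral
    header_title: "RNFL OU ANALYSIS REPORT"
    header_box: [16, 12, 390, 46]
    page_size: [560, 420]
    version_range: "1.7.0.0-1.10.4.0"
    fields:
      - {name: patient_id, kind: text, box: [402, 14, 552, 40], pattern: "\\d{8}"}
      - {name: visit_date, kind: date, box: [402, 44, 552, 70]}
      - {name: od_avg_rnfl_thickness, kind: numeric, box: [90, 120, 215, 152],
         unit: "µm", pattern: "\\d{2,3}", eye: right}
      - {name: os_avg_rnfl_thickness, kind: numeric, box: [335, 120, 460, 152],
         unit: "µm", pattern: "\\d{2,3}", eye: left}
      - {name: od_superior_rnfl_thickness, kind: numeric, box: [90, 170, 215, 202],
         unit: "µm", pattern: "\\d{2,3}", eye: right}
      - {name: os_superior_rnfl_thickness, kind: numeric, box: [335, 170, 460, 202],
         unit: "µm", pattern: "\\d{2,3}", eye: left}
  - type_id: macula_current
    header_title: "MACULAR THICKNESS REPORT"
    header_box: [16, 12, 390, 46]
    page_size: [560, 420]
    version_range: "1.7.0.0-1.10.4.0"
    fields:
      - {name: patient_id, kind: text, box: [402, 14, 552, 40], pattern: "\\d{8}"}
      - {name: visit_date, kind: date, box: [402, 44, 552, 70]}
      - {name: laterality, kind: text, box: [24, 60, 150, 86], pattern: "RIGHT|LEFT"}
      - {name: total_macular_volume, kind: numeric, box: [210, 110, 330, 142],
         unit: "mm³", pattern: "\\d+\\.\\d{2}"}
      - {name: central_macular_thickness, kind: numeric, box: [210, 160, 330, 192],
         unit: "µm", pattern: "\\d{2,3}"}
      - {name: macula_scan, kind: tomogram, box: [60, 230, 500, 400]}
  - type_id: macula_prev_current
    header_title: "MACULAR THICKNESS CHANGE REPORT"
    header_box: [16, 12, 390, 46]
    page_size: [560, 420]
    version_range: "1.7.0.0-1.10.4.0"
    fields:
      - {name: patient_id, kind: text, box: [402, 14, 552, 40], pattern: "\\d{8}"}
      - {name: visit_date, kind: date, box: [402, 44, 552, 70]}
      - {name: laterality, kind: text, box: [24, 60, 150, 86], pattern: "RIGHT|LEFT"}
      - {name: prev_total_macular_volume, kind: numeric, box: [60, 110, 180, 142],
         unit: "mm³", pattern: "\\d+\\.\\d{2}"}
      - {name: total_macular_volume, kind: numeric, box: [330, 110, 450, 142],
         unit: "mm³", pattern: "\\d+\\.\\d{2}"}
      - {name: prev_central_macular_thickness, kind: numeric, box: [60, 160, 180, 192],
         unit: "µm", pattern: "\\d{2,3}"}
      - {name: central_macular_thickness, kind: numeric, box: [330, 160, 450, 192],
         unit: "µm", pattern: "\\d{2,3}"}
      - {name: macula_scan, kind: tomogram, box: [60, 230, 500, 400]}
  - type_id: macula_scan_current
    header_title: "MACULA SCAN REPORT"
    header_box: [16, 12, 390, 46]
    page_size: [560, 420]
    version_range: "1.7.0.0-1.10.4.0"
    fields:
      - {name: patient_id, kind: text, box: [402, 14, 552, 40], pattern: "\\d{8}"}
      - {name: visit_date, kind: date, box: [402, 44, 552, 70]}
      - {name: laterality, kind: text, box: [24, 60, 150, 86], pattern: "RIGHT|LEFT"}
      - {name: horizontal_scan, kind: tomogram, box: [30, 100, 530, 250]}
      - {name: vertical_scan, kind: tomogram, box: [30, 260, 530, 410]}
  - type_id: macula_scan_prev_current
    header_title: "MACULA SCAN COMPARISON REPORT"
    header_box: [16, 12, 390, 46]
    page_size: [560, 420]
    version_range: "1.7.0.0-1.10.4.0"
    fields:
      - {name: patient_id, kind: text, box: [402, 14, 552, 40], pattern: "\\d{8}"}
      - {name: visit_date, kind: date, box: [402, 44, 552, 70]}
      - {name: laterality, kind: text, box: [24, 60, 150, 86], pattern: "RIGHT|LEFT"}
      - {name: prev_horizontal_scan, kind: tomogram, box: [30, 100, 275, 245]}
      - {name: horizontal_scan, kind: tomogram, box: [285, 100, 530, 245]}
      - {name: prev_vertical_scan, kind: tomogram, box: [30, 260, 275, 405]}
      - {name: vertical_scan, kind: tomogram, box: [285, 260, 530, 405]}
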