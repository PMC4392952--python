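{
  "description": "Printed per-group summary statistics (mean, SD) from the diabetic-rat hippocampus study this package emulates. Four arms: Con (control), Ins (insulin-treated diabetic), VitC (vitamin-C-treated diabetic), Dia (untreated diabetic), N = 10 animals each.",
  "volume_mm3": {
    "DG": {
      "Con": [2.00, 0.09],
      "Ins": [1.99, 0.07],
      "VitC": [1.64, 0.04],
      "Dia": [1.58, 0.04]
    },
    "CA3": {
      "Con": [3.15, 0.2],
      "Ins": [3.08, 0.2],
      "VitC": [2.06, 0.12],
      "Dia": [1.98, 0.08]
    }
  },
  "density_per_mm3": {
    "DG": {
      "Con": [945, 106],
      "Ins": [1074, 154],
      "VitC": [1119, 220],
      "Dia": [9615, 264]
    },
    "CA3": {
      "Con": [613, 230],
      "Ins": [616, 159],
      "VitC": [798, 137],
      "Dia": [18055, 3842]
    }
  },
  "blood_glucose_mg_dl": {
    "Con": [101, 6.3],
    "Ins": [114.5, 15.3],
    "VitC": [487.5, 83.35],
    "Dia": [568, 45.2]
  },
  "plasma_cu_ug_dl": {
    "Con": [7.29, 0.08],
    "Ins": [7.29, 0.1],
    "VitC": [7.22, 0.11],
    "Dia": [8.0, 0.5]
  },
  "notes": {
    "plasma_cu_ug_dl.Dia": "synthetic default: the diabetic-group Cu level was shown only graphically (elevated relative to the other arms), never as a number; 8.0 +/- 0.5 is this package's stand-in value"
  },
  "published_response_index": {
    "volume": {"Con": 0.63, "Ins": 0.64, "VitC": 0.81, "Dia": 0.80},
    "density": {"Con": 1.54, "Ins": 1.74, "VitC": 1.40, "Dia": 0.53}
  },
  "correlation_targets": {
    "order": ["V_DG", "V_CA3", "ND_DG", "ND_CA3", "BG", "Cu"],
    "matrix": [
      [1.0, 0.9, -0.6, -0.6, -0.9, -0.6],
      [0.9, 1.0, -0.6, -0.6, -0.9, -0.7],
      [-0.6, -0.6, 1.0, 0.97, 0.72, 0.99],
      [-0.6, -0.6, 0.97, 1.0, 0.75, 0.99],
      [-0.9, -0.9, 0.72, 0.75, 1.0, 0.7],
      [-0.6, -0.7, 0.99, 0.99, 0.7, 1.0]
    ],
    "note": "pairwise targets as reported; unreported pairs filled with plausible values. Not jointly positive semi-definite; the generator's default is the nearest correlation matrix (Higham projection) of this matrix."
  }
}
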