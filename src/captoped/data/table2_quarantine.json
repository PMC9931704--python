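{
  "description": "Printed PK-parameter table cells that are internally inconsistent (do not reproduce from the other printed cells of the same row at 2-decimal rounding). Kept verbatim in table2.csv, excluded from parity assertions, never silently corrected.",
  "conventions": {
    "identity": "CL/F = dose * 1e6 / AUC (ng*h/ml -> ml/h -> /1000 L/h); per-kg doses give L/h/kg",
    "ratio": "ratio = predicted / observed, rounded to 2 dp"
  },
  "cells": [
    {
      "id": "RF6",
      "cell": "clf_obs",
      "printed": 0.09,
      "recomputed": 0.93,
      "note": "dose/AUC = 2e6/2153.50 = 0.93 L/h/kg; printed value looks like a decimal-shift typo"
    },
    {
      "id": "RF6",
      "cell": "clf_pred",
      "printed": 0.07,
      "recomputed": 0.67,
      "note": "dose/AUC = 2e6/2978.25 = 0.67 L/h/kg; same decimal-shift pattern as clf_obs"
    },
    {
      "id": "RS1",
      "cell": "clf_pred",
      "printed": 28.65,
      "recomputed": 28.67,
      "note": "predicted AUC printed at 3 significant figures (436); 12.5e6/436 = 28.67"
    },
    {
      "id": "RS2",
      "cell": "clf_pred",
      "printed": 55.36,
      "recomputed": 55.40,
      "note": "predicted AUC printed at 3 significant figures (361); 20e6/361 = 55.40"
    },
    {
      "id": "RS5",
      "cell": "auc_ratio",
      "printed": 0.6,
      "recomputed": 0.59,
      "note": "635.37/1082.10 = 0.587 -> 0.59"
    },
    {
      "id": "RF2",
      "cell": "clf_ratio",
      "printed": 2.29,
      "recomputed": 2.31,
      "note": "1.64/0.71 = 2.31 (and AUC_obs/AUC_pred = 2.31)"
    },
    {
      "id": "RF5",
      "cell": "clf_ratio",
      "printed": 0.82,
      "recomputed": 0.92,
      "note": "1.44/1.56 = 0.92; also inconsistent with 1/auc_ratio = 0.93"
    },
    {
      "id": "RF3",
      "cell": "clf_ratio",
      "printed": 0.72,
      "recomputed": 0.88,
      "note": "1.02/1.16 = 0.88"
    },
    {
      "id": "RF4",
      "cell": "clf_ratio",
      "printed": 0.81,
      "recomputed": 1.05,
      "note": "0.98/0.93 = 1.05"
    },
    {
      "id": "RF6",
      "cell": "clf_ratio",
      "printed": 0.47,
      "recomputed": 0.78,
      "note": "0.07/0.09 = 0.78; 0.72 from the unshifted 0.67/0.93"
    },
    {
      "id": "RS7",
      "cell": "clf_ratio",
      "printed": 1.09,
      "recomputed": 1.1,
      "note": "49.79/45.27 = 1.0998 -> 1.10"
    }
  ]
}
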