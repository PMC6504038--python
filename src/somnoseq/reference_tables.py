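"""Published benchmark confusion matrices for the metrics stack.

These are the pooled 20-fold cross-validation confusion matrices reported
for sequence-to-sequence sleep staging on the Sleep-EDF-13 corpus, one per
EEG derivation (Fpz-Cz and Pz-Oz). Rows are the expert reference stages,
columns the predicted stages, in W, N1, N2, N3, REM order. They serve as
fixed integer inputs for exercising and validating the evaluation stack
(per-class metrics, accuracy, macro-F1, Cohen's κ) against the metric
values published alongside them.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix

#: Pooled confusion matrix, Fpz-Cz channel, Sleep-EDF-13, 20-fold CV.
FPZ_CZ_CONFUSION = ConfusionMatrix(np.array([
    [7161,  432,    67,   27,  219],
    [ 442, 1486,   364,   25,  409],
    [ 359,  735, 14187, 1035,  837],
    [  37,    9,   560, 4857,    2],
    [ 153,  307,   368,    2, 6520],
]))

#: Pooled confusion matrix, Pz-Oz channel, Sleep-EDF-13, 20-fold CV.
PZ_OZ_CONFUSION = ConfusionMatrix(np.array([
    [7094,  398,    82,   41,  238],
    [ 539, 1167,   455,   29,  492],
    [ 114,  655, 14220, 1157,  971],
    [  17,   12,   791, 4658,   10],
    [ 100,  314,   506,   50, 6489],
]))

#: Overall metrics published with the matrices above (percent / unitless κ).
PUBLISHED_OVERALL = {
    "fpz_cz": {"accuracy": 84.26, "macro_f1": 79.66, "kappa": 0.79},
    "pz_oz": {"accuracy": 82.83, "macro_f1": 77.02, "kappa": 0.77},
}

#: Per-class percentages published with the matrices (Pre, Rec, Spe, F1).
PUBLISHED_PER_CLASS = {
    "fpz_cz": {
        "W":   {"precision": 87.84, "recall": 90.58, "specificity": 96.97, "f1": 89.19},
        "N1":  {"precision": 50.05, "recall": 54.51, "specificity": 96.08, "f1": 52.19},
        "N2":  {"precision": 91.26, "recall": 82.71, "specificity": 94.20, "f1": 86.77},
        "N3":  {"precision": 81.69, "recall": 88.87, "specificity": 96.90, "f1": 85.13},
        "REM": {"precision": 81.63, "recall": 88.71, "specificity": 95.59, "f1": 85.02},
    },
    "pz_oz": {
        "W":   {"precision": 90.20, "recall": 90.33, "specificity": 97.65, "f1": 90.27},
        "N1":  {"precision": 45.84, "recall": 43.51, "specificity": 96.36, "f1": 44.64},
        "N2":  {"precision": 88.58, "recall": 83.07, "specificity": 92.19, "f1": 85.74},
        "N3":  {"precision": 78.48, "recall": 84.88, "specificity": 96.36, "f1": 81.55},
        "REM": {"precision": 79.13, "recall": 87.00, "specificity": 94.84, "f1": 82.88},
    },
}
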