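"""Published reference results for the five-class CT tissue segmentation.

``REFERENCE_CONFUSION`` is the pixel confusion matrix of the original
clinically trained segmentation model on its 378-image test set (rows =
actual class, columns = predicted class, order air, muscle/water, fat,
skin, fibrosis).  It is shipped so that the metric implementations can be
validated against the published per-class accuracy/IoU/DSC figures without
access to the clinical images.

The published per-class metric table is reproducible from this matrix for
air, fat, skin and fibrosis; the published muscle/water row is not
consistent with the matrix under any row/column reading and is therefore
not included among the reconcilable reference values.
"""

from __future__ import annotations

import numpy as np

from fibroquant.seg_metrics import ConfusionMatrix

__all__ = ["REFERENCE_CONFUSION", "REFERENCE_SCORES"]

REFERENCE_CONFUSION = ConfusionMatrix(np.array([
    #  air      muscle/water   fat       skin     fibrosis
    [19362257,        0,            0,        9,        0],   # air
    [      60, 12848499,        17059,      977,    69293],   # muscle/water
    [       0,    33531,      1190847,     3354,   136657],   # fat
    [       1,       36,        15746,   447883,     4348],   # skin
    [       0,    39396,        62347,    42085,   497700],   # fibrosis
]))

# published per-class figures that reconcile exactly with the matrix
REFERENCE_SCORES = {
    ("fibrosis", "accuracy"): 0.776,
    ("fibrosis", "iou"): 0.584,
    ("fibrosis", "dsc"): 0.738,
    ("skin", "accuracy"): 0.957,
    ("skin", "iou"): 0.871,
    ("skin", "dsc"): 0.931,
    ("fat", "accuracy"): 0.873,
    ("fat", "iou"): 0.816,
    ("fat", "dsc"): 0.899,
    ("air", "accuracy"): 0.999,
}
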