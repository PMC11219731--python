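"""Reported pathologist-scoring confusion matrices for benchmarking.

These are the published rater-vs-IHC-consensus cross-tabulations from the
28-case NSCLC cohort behind this pipeline (two pathologists, each scoring
medium-exposure IF images and HDR-processed images into the three TPS
categories), plus the 16-case subset restricted to TPS >= 1%.  Rows are the
pathologist's calls, columns the IHC consensus, category order
(<1%, 1-49%, >=50%).  They serve as fixed inputs for validating the
agreement statistics against the published accuracy and kappa values.
"""

from __future__ import annotations

import numpy as np

from .agreement import ConfusionMatrix
from .quant import TPS_CATEGORIES


def _cm(rows: list[list[int]]) -> ConfusionMatrix:
    return ConfusionMatrix(counts=np.array(rows), categories=TPS_CATEGORIES)


#: All 28 cases, pathologist x modality -> (matrix, reported accuracy %,
#: reported weighted kappa).
ALL_CASES = {
    ("pathologist1", "IF-MED"): (_cm([[11, 1, 0], [1, 7, 0], [0, 3, 5]]), 82.1, 0.78),
    ("pathologist1", "HDR"): (_cm([[10, 1, 0], [2, 8, 0], [0, 2, 5]]), 82.1, 0.78),
    ("pathologist2", "IF-MED"): (_cm([[12, 7, 0], [0, 4, 3], [0, 0, 2]]), 64.3, 0.56),
    ("pathologist2", "HDR"): (_cm([[10, 2, 0], [2, 9, 0], [0, 0, 5]]), 85.7, 0.83),
}

#: The 16-case subset with consensus TPS >= 1%.
TPS_GE_1_SUBSET = {
    ("pathologist1", "IF-MED"): (_cm([[0, 1, 0], [0, 7, 0], [0, 3, 5]]), 75.0, 0.71),
    ("pathologist1", "HDR"): (_cm([[0, 1, 0], [0, 8, 0], [0, 2, 5]]), 81.3, 0.79),
    ("pathologist2", "IF-MED"): (_cm([[0, 7, 0], [0, 4, 3], [0, 0, 2]]), 37.5, 0.29),
    ("pathologist2", "HDR"): (_cm([[0, 2, 0], [0, 9, 0], [0, 0, 5]]), 87.5, 0.86),
}

#: Reported interobserver kappas (pathologist 1 vs 2) per modality.
INTEROBSERVER_KAPPA = {"IHC": 0.91, "IF-MED": 0.39, "HDR": 0.69}
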