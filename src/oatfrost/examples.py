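"""Worked-example data for the accuracy-assessment machinery.

The fuzzy error matrix below is a synthetic reconstruction of a field
validation of a four-class oat frost-damage map: 200 reference polygons
scored pixel-weighted against the classified image, for a sampled
surface of 68,800 units.  Its diagonal counts, row/column totals and the
two fully specified off-diagonal cells are fixed to the published
marginal figures of that survey style; the remaining off-diagonal cells,
which only the marginals constrain, were completed synthetically so the
matrix is internally consistent.  It exercises every accuracy measure
with realistic magnitudes.
"""

from __future__ import annotations

import numpy as np

from .validation import FuzzyErrorMatrix

__all__ = ["synthetic_survey_matrix"]


def synthetic_survey_matrix() -> FuzzyErrorMatrix:
    """Four-class (GO, DO, HD, SG) fuzzy error matrix, pixel-weighted.

    Rows are the classifier's assignments, columns the expert reference.
    Off-diagonal cells are (acceptable, unacceptable) pairs.
    """
    classes = ("GO", "DO", "HD", "SG")
    correct = np.array([22600, 8800, 9200, 22800])
    acceptable = np.array(
        [
            [0, 600, 400, 0],
            [600, 0, 0, 0],
            [0, 600, 0, 0],
            [0, 0, 600, 0],
        ]
    )
    unacceptable = np.array(
        [
            [0, 600, 600, 0],
            [400, 0, 0, 0],
            [0, 200, 0, 0],
            [400, 0, 400, 0],
        ]
    )
    return FuzzyErrorMatrix(classes, correct, acceptable, unacceptable)
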