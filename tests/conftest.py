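"""Shared fixtures: the bundled model and a cross-tabulation cohort.

``reference_cohort`` reconstructs a 144-subject validation cohort from its
published cross-tabulated counts: each subject gets a representative
protein intake (below 0.8, between 0.8 and 1.0, or at/above 1.0 g/kg
aBW/d) and a representative screener score inside one of the four
probability bins bounded by the reporting cut-offs 0.3/0.5/0.7. The joint
counts are chosen so that both cut-off tables (reference < 1.0 and < 0.8
g/kg aBW/d) are reproduced exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from pro55.screener import ScreenerModel, load_default_model

# (protein g/kg aBW/d, counts per score bin [<=0.3, <=0.5, <=0.7, >0.7])
# rows: intake < 0.8; 0.8 <= intake < 1.0; intake >= 1.0
_JOINT_COUNTS = (
    (0.70, (9, 4, 5, 7)),
    (0.90, (18, 7, 1, 6)),
    (1.15, (58, 15, 5, 9)),
)
_BIN_SCORES = (0.20, 0.40, 0.60, 0.80)


def build_reference_cohort() -> tuple[np.ndarray, np.ndarray]:
    """Scores and protein intakes for the 144-subject count-table cohort."""
    scores, protein = [], []
    for intake, bins in _JOINT_COUNTS:
        for score, count in zip(_BIN_SCORES, bins):
            scores.extend([score] * count)
            protein.extend([intake] * count)
    return np.asarray(scores), np.asarray(protein)


@pytest.fixture(scope="session")
def reference_cohort() -> tuple[np.ndarray, np.ndarray]:
    return build_reference_cohort()


@pytest.fixture(scope="session")
def model() -> ScreenerModel:
    return load_default_model()
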