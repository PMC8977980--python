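"""Worked-example fixtures: printed counts from a published cohort.

These per-patient tables are reconstructed exactly from the contingency
counts printed in a published 85-patient persistent/long-standing AF
driver-mapping study (64 men, 21 women; recurrence analysed in the 79
patients past the 90-day blanking period). Only the counts are encoded —
covariates are not part of these fixtures — so every statistic computed
from them is an exact reproduction of the corresponding published figure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: (n, recurrences) by RAc-location class among the 79 followed patients
RECURRENCE_BY_RAC_LOCATION_COUNTS = {
    "none": (29, 9),
    "inside_only": (9, 1),
    "outside": (41, 26),
}

#: (n, with RAc) by gender in the full 85-patient cohort
RAC_BY_GENDER_COUNTS = {"M": (64, 47), "F": (21, 8)}


def reference_recurrence_cohort() -> pd.DataFrame:
    """Per-patient frame with ``rac_location_class`` and ``recurrence``.

    79 rows expanding :data:`RECURRENCE_BY_RAC_LOCATION_COUNTS`.
    """
    rows = []
    for loc, (n, rec) in RECURRENCE_BY_RAC_LOCATION_COUNTS.items():
        for i in range(n):
            rows.append(
                dict(
                    rac_location_class=loc,
                    recurrence=int(i < rec),
                    followup_days=365.0,
                )
            )
    return pd.DataFrame(rows)


def reference_gender_rac_cohort() -> pd.DataFrame:
    """Per-patient frame with ``gender`` and ``has_rac`` (85 rows)."""
    rows = []
    for gender, (n, rac) in RAC_BY_GENDER_COUNTS.items():
        for i in range(n):
            rows.append(dict(gender=gender, has_rac=int(i < rac)))
    return pd.DataFrame(rows)


def gender_rac_contingency() -> np.ndarray:
    """2x2 table [[men RAc, men no-RAc], [women RAc, women no-RAc]]."""
    (nm, rm), (nw, rw) = RAC_BY_GENDER_COUNTS["M"], RAC_BY_GENDER_COUNTS["F"]
    return np.array([[rm, nm - rm], [rw, nw - rw]])
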