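"""Printed study inputs.

The semen-parameter table for the ten normozoospermic subjects is part of the
published record and is used as an input (cohort description and an
arithmetic check on the analysis tables).
"""

from __future__ import annotations

import pandas as pd

_SEMEN_ROWS = [
    # subject, age, concentration (10^6/ml), motility (%), progressive (%), normal forms (%)
    (1, 32, 125, 96, 80, 4),
    (2, 33, 60, 87, 80, 4),
    (3, 43, 137, 80, 76, 6),
    (4, 48, 133, 98, 92, 5),
    (5, 30, 70, 91, 87, 5),
    (6, 42, 66, 68, 60, 10),
    (7, 29, 92, 78, 60, 6),
    (8, 38, 48, 73, 57, 4),
    (9, 29, 50, 90, 66, 4),
    (10, 35, 48, 59, 54, 4),
]

#: Printed per-column means for the ten subjects.
SEMEN_PARAMETER_MEANS = {
    "age": 35.9,
    "concentration": 82.9,
    "motility": 82.0,
    "progressive_motility": 71.2,
    "normal_forms": 5.2,
}


def semen_parameters() -> pd.DataFrame:
    """Semen parameters of the ten enrolled subjects (WHO 2010 normozoospermic)."""
    return pd.DataFrame(
        _SEMEN_ROWS,
        columns=[
            "subject",
            "age",
            "concentration",
            "motility",
            "progressive_motility",
            "normal_forms",
        ],
    )
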