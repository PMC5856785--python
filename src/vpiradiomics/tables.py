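"""Published cohort summaries used as reference inputs.

These are the printed per-feature distribution parameters and pathology
contingency counts of the 327-patient study cohort (192 VPI−, 135 VPI+).
They parameterize the synthetic cohort generator and the cohort-summary
recomputations; the underlying per-patient CT data are not public.
"""

from __future__ import annotations

import pandas as pd

#: Study cohort sizes: (VPI−, VPI+).
COHORT_SIZES = (192, 135)

#: Per-class (mean, SD) of the five top-ranked signature features,
#: keyed by catalog name; value = ((mean−, sd−), (mean+, sd+)).
#: Units: HU for the percentile, matrix-statistic units otherwise.
SIGNATURE_FEATURE_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "Perc.10%": ((-420.0, 136.0), (-211.0, 104.0)),
    "WavEnLL_s-2": ((1378.0, 621.0), (3075.0, 522.0)),
    "S(0,1)SumAverage": ((19.20, 10.11), (30.65, 6.07)),
    "45dgr_GLevNonU": ((20.73, 15.11), (98.7, 40.3)),
    "S(3,3)Contrast": ((14.41, 6.36), (10.01, 5.78)),
}


def predominant_subtype_table() -> pd.DataFrame:
    """Lesion counts by predominant histological subtype × VPI status."""
    data = {
        "LPA": (78, 22),
        "Acinar": (86, 64),
        "Papillary": (15, 12),
        "MP": (5, 17),
        "Solid": (0, 9),
        "Mucinous": (8, 11),
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["vpi_neg", "vpi_pos"]
    )


def pathological_grade_table() -> pd.DataFrame:
    """Lesion counts by pathological grade × VPI status."""
    data = {
        "Grade I": (43, 0),
        "Grade II": (144, 115),
        "Grade III": (5, 20),
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["vpi_neg", "vpi_pos"]
    )
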