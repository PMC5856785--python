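"""First-order (histogram) intensity features.

Nine statistics of the in-mask HU distribution: mean, variance, skewness,
kurtosis and the 1/10/50/90/99 lower percentiles.  The 10th percentile is
the point below which 10% of the voxel values lie, counting from the left
of the histogram; percentiles use linear interpolation between order
statistics.  Moments are population moments (divide by n); kurtosis is the
Fisher (excess) convention.  With fewer than two distinct values the
skewness and kurtosis are undefined and returned as NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..catalog import HISTOGRAM_FEATURES
from ..voi import VOI

_PERCENTILES = {"Perc.01%": 1, "Perc.10%": 10, "Perc.50%": 50,
                "Perc.90%": 90, "Perc.99%": 99}


def histogram_features(voi: VOI) -> dict[str, float]:
    values = voi.masked_values()
    out: dict[str, float] = {}
    out["Mean"] = float(values.mean())
    var = float(values.var())  # population variance
    out["Variance"] = var
    if var == 0.0:
        out["Skewness"] = float("nan")
        out["Kurtosis"] = float("nan")
    else:
        out["Skewness"] = float(stats.skew(values, bias=True))
        out["Kurtosis"] = float(stats.kurtosis(values, fisher=True, bias=True))
    for name, q in _PERCENTILES.items():
        out[name] = float(np.percentile(values, q, method="linear"))
    assert tuple(out) == HISTOGRAM_FEATURES
    return out
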