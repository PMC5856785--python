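"""Full-catalog feature extraction for a VOI.

``extract_all`` returns the 308 catalog features in canonical order as a
pandas Series.  Statistics that are undefined for a degenerate region (for
example a co-occurrence offset admitting no in-mask pair, or shape ratios
of a single voxel) are returned as NaN so the vector length is invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..catalog import (
    GLCM_OFFSETS,
    GLCM_STATISTICS,
    GLRLM_DIRECTIONS,
    GLRLM_POOLED,
    GLRLM_STATISTICS,
    catalog_names,
    glcm_feature_name,
    glrlm_feature_name,
)
from ..exceptions import EmptyMatrixError
from ..voi import VOI
from .glcm import glcm, glcm_features
from .glrlm import glrlm, glrlm_features, pooled_glrlm
from .histogram import histogram_features
from .quantize import quantize
from .shape import shape_features
from .wavelet import wavelet_energies


def extract_all(voi: VOI, n_levels: int = 64) -> pd.Series:
    """Compute the full 308-feature catalog for one VOI.

    Parameters
    ----------
    voi : VOI with a non-empty mask.
    n_levels : gray levels for texture quantization (default 64).

    Returns
    -------
    pandas.Series of length 308 indexed by catalog feature names.
    """
    values: dict[str, float] = {}
    values.update(shape_features(voi.mask, voi.spacing))
    values.update(histogram_features(voi))

    q = quantize(voi, n_levels=n_levels)
    L = int(q[voi.mask].max())
    for offset in GLCM_OFFSETS:
        try:
            stats = glcm_features(glcm(q, voi.mask, offset, n_levels=L))
        except EmptyMatrixError:
            stats = {s: float("nan") for s in GLCM_STATISTICS}
        for s, v in stats.items():
            values[glcm_feature_name(offset, s)] = v

    matrices = []
    for direction in GLRLM_DIRECTIONS:
        r = glrlm(q, voi.mask, direction, n_levels=L)
        matrices.append(r)
        for s, v in glrlm_features(r).items():
            values[glrlm_feature_name(direction, s)] = v
    pooled = glrlm_features(pooled_glrlm(matrices))
    for name, stat in zip(GLRLM_POOLED, ("GLevNonU", "RLNonUni", "Fraction")):
        values[name] = pooled[stat]

    values.update(wavelet_energies(voi))

    order = catalog_names()
    vec = pd.Series([values[n] for n in order], index=order, dtype=float,
                    name=voi.case_id or None)
    return vec


def extract_cohort(vois, labels=None, n_levels: int = 64) -> pd.DataFrame:
    """Extract the catalog for a sequence of VOIs into a cases×features table.

    If ``labels`` is given, a ``label`` column is prepended.
    """
    rows = []
    ids = []
    for k, voi in enumerate(vois):
        rows.append(extract_all(voi, n_levels=n_levels))
        ids.append(voi.case_id or f"case{k:04d}")
    table = pd.DataFrame(rows)
    table.index = pd.Index(ids, name="case_id")
    if labels is not None:
        table.insert(0, "label", np.asarray(labels, dtype=int))
    return table
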