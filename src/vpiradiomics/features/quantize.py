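"""Gray-level quantization of the in-mask intensity range."""

from __future__ import annotations

import numpy as np

from ..exceptions import DegenerateMaskError, ParameterError
from ..voi import VOI


def quantize(voi: VOI, n_levels: int = 64) -> np.ndarray:
    """Map in-mask voxels to integer levels ``1..n_levels``.

    Equal-width binning of the in-mask [min, max] range; a constant region
    maps everything to level 1.  Outside-mask voxels are 0.

    Parameters
    ----------
    voi : VOI
    n_levels : int
        Number of gray levels, >= 2 (default 64).

    Returns
    -------
    ndarray of int, same shape as the VOI grid.
    """
    if n_levels < 2:
        raise ParameterError("n_levels must be >= 2")
    if not voi.mask.any():
        raise DegenerateMaskError("cannot quantize an empty mask")
    values = voi.intensities[voi.mask]
    lo, hi = float(values.min()), float(values.max())
    out = np.zeros(voi.intensities.shape, dtype=np.int32)
    if hi == lo:
        out[voi.mask] = 1
        return out
    scaled = (voi.intensities[voi.mask] - lo) / (hi - lo) * n_levels
    levels = np.floor(scaled).astype(np.int32) + 1
    np.clip(levels, 1, n_levels, out=levels)
    out[voi.mask] = levels
    return out
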