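"""Gray-level run-length matrices and their statistics.

Runs are maximal sequences of equal-level in-mask voxels along one of four
directions within each axial slice (0° rows, 90° columns, 45°/135°
diagonals); out-of-mask voxels break runs.  Run counts are summed over
slices.  Seven statistics are computed per direction, plus three aggregates
on the runs pooled over all four directions.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import DegenerateMaskError, EmptyMatrixError
from ..catalog import GLRLM_DIRECTIONS, GLRLM_STATISTICS

# (row step, column step) per direction; sign is irrelevant for runs.
_DIRECTION_STEPS = {
    "0dgr": (0, 1),
    "45dgr": (-1, 1),
    "90dgr": (1, 0),
    "135dgr": (1, 1),
}


def glrlm(quantized: np.ndarray, mask: np.ndarray, direction: str,
          n_levels: int | None = None) -> np.ndarray:
    """Run-length matrix ``r[g-1, l-1]`` = number of runs of level g, length l."""
    if direction not in _DIRECTION_STEPS:
        raise ValueError(f"unknown direction {direction!r}; "
                         f"expected one of {GLRLM_DIRECTIONS}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateMaskError("empty mask")
    if n_levels is None:
        n_levels = int(quantized[mask].max())
    max_len = max(quantized.shape[1], quantized.shape[2])
    r = np.zeros((n_levels, max_len), dtype=np.int64)
    for s in range(quantized.shape[0]):
        if not mask[s].any():
            continue
        seq = np.where(mask[s], quantized[s], 0)
        for line in _lines(seq, direction):
            _count_runs(line, r)
    return r


def _lines(seq: np.ndarray, direction: str):
    """Yield the 1D gray-level lines of a slice along a direction (0 = gap)."""
    if direction == "0dgr":
        yield from seq
    elif direction == "90dgr":
        yield from seq.T
    else:
        a = seq[::-1] if direction == "45dgr" else seq
        H, W = a.shape
        for off in range(-H + 1, W):
            yield np.diagonal(a, offset=off)


def _count_runs(line: np.ndarray, r: np.ndarray) -> None:
    n = line.size
    if n == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    levels = line[starts]
    lengths = ends - starts
    keep = levels > 0
    np.add.at(r, (levels[keep] - 1, lengths[keep] - 1), 1)


def glrlm_features(r: np.ndarray) -> dict[str, float]:
    """Seven run-length statistics of a run-length matrix."""
    r = np.asarray(r, dtype=float)
    R = r.sum()
    if R == 0:
        raise EmptyMatrixError("run-length matrix has no runs")
    g = np.arange(1, r.shape[0] + 1)
    l = np.arange(1, r.shape[1] + 1)
    r_g = r.sum(axis=1)  # runs per gray level
    r_l = r.sum(axis=0)  # runs per length
    n_vox = float((l * r_l).sum())  # voxels traversed
    out: dict[str, float] = {}
    out["ShrtREmph"] = float((r_l / l ** 2).sum() / R)
    out["LngREmph"] = float((r_l * l ** 2).sum() / R)
    out["GLevNonU"] = float((r_g ** 2).sum() / R)
    out["RLNonUni"] = float((r_l ** 2).sum() / R)
    out["Fraction"] = float(R / n_vox)
    out["LowGREmph"] = float((r_g / g ** 2).sum() / R)
    out["HighGREmph"] = float((r_g * g ** 2).sum() / R)
    assert tuple(out) == GLRLM_STATISTICS
    return out


def pooled_glrlm(matrices: list[np.ndarray]) -> np.ndarray:
    """Sum run-length matrices over directions, padding to a common shape."""
    G = max(m.shape[0] for m in matrices)
    L = max(m.shape[1] for m in matrices)
    total = np.zeros((G, L), dtype=np.int64)
    for m in matrices:
        total[: m.shape[0], : m.shape[1]] += m
    return total
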