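"""Gray-level co-occurrence matrices and their 12 Haralick-type statistics.

Co-occurrence is counted per axial slice for a 2D offset ``(d1, d2)`` in
(row, column) units; only voxel pairs with both ends inside the mask count.
Counts are summed over slices, symmetrized and normalized to sum 1.
Entropies use the natural logarithm; the correlation of a constant region
is undefined and returned as NaN.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import EmptyMatrixError
from ..catalog import GLCM_STATISTICS


def glcm(quantized: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
         n_levels: int | None = None) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix for one slice offset.

    Parameters
    ----------
    quantized : 3D int array, levels 1..L in-mask (0 outside).
    mask : 3D bool array, aligned.
    offset : (d1, d2) displacement in (row, column) within each axial slice.
    n_levels : matrix size L; defaults to the in-mask maximum level.

    Returns
    -------
    (L, L) float array summing to 1, with p[i-1, j-1] = p(i, j).
    """
    mask = np.asarray(mask, dtype=bool)
    if n_levels is None:
        if not mask.any():
            raise EmptyMatrixError("empty mask")
        n_levels = int(quantized[mask].max())
    dr, dc = offset
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for s in range(quantized.shape[0]):
        a, m = quantized[s], mask[s]
        if not m.any():
            continue
        _accumulate_pairs(a, m, dr, dc, counts)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise EmptyMatrixError(f"no in-mask voxel pairs admit offset {offset}")
    return counts / total


def _accumulate_pairs(a: np.ndarray, m: np.ndarray, dr: int, dc: int,
                      counts: np.ndarray) -> None:
    H, W = a.shape
    if abs(dr) >= H or abs(dc) >= W:
        return
    r_src = slice(max(0, -dr), H - max(0, dr))
    c_src = slice(max(0, -dc), W - max(0, dc))
    r_dst = slice(max(0, dr), H - max(0, -dr))
    c_dst = slice(max(0, dc), W - max(0, -dc))
    valid = m[r_src, c_src] & m[r_dst, c_dst]
    i = a[r_src, c_src][valid] - 1
    j = a[r_dst, c_dst][valid] - 1
    np.add.at(counts, (i, j), 1)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 12 co-occurrence statistics of a normalized symmetric matrix."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    L = p.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    # gray-level sum / difference distributions
    ks = np.arange(2, 2 * L + 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    kd = np.arange(0, L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    out: dict[str, float] = {}
    out["AngScMom"] = float((p ** 2).sum())
    out["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0:
        out["Correlat"] = float(((ii * jj * p).sum() - mu_x * mu_x) / var_x)
    else:
        out["Correlat"] = float("nan")
    out["SumOfSqs"] = var_x
    out["InvDfMom"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((ks * p_sum).sum())
    out["SumAverage"] = sum_avg
    out["SumVarnc"] = float(((ks - sum_avg) ** 2 * p_sum).sum())
    out["SumEntrp"] = _entropy(p_sum)
    out["Entropy"] = _entropy(p)
    diff_avg = float((kd * p_diff).sum())
    out["DifVarnc"] = float(((kd - diff_avg) ** 2 * p_diff).sum())
    out["DifEntrp"] = _entropy(p_diff)
    out["Dissim"] = float((np.abs(ii - jj) * p).sum())
    assert tuple(out) == GLCM_STATISTICS
    return out
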