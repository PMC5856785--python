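"""Feature-extraction correctness against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

import pywt
from skimage.feature import graycomatrix

from vpiradiomics import VOI, catalog_names, catalog_groups
from vpiradiomics.exceptions import DegenerateMaskError, EmptyMatrixError, ParameterError
from vpiradiomics.features import (
    extract_all, glcm, glcm_features, glrlm, glrlm_features, histogram_features,
    pooled_glrlm, quantize, shape_features, wavelet_energies,
)
from vpiradiomics.features.glrlm import _DIRECTION_STEPS

from conftest import make_voi


# --------------------------------------------------------------------- oracles

def glcm_oracle(quantized, mask, offset, n_levels):
    """Literal pair enumeration: count, symmetrize, normalize."""
    dr, dc = offset
    counts = np.zeros((n_levels, n_levels))
    S, H, W = quantized.shape
    for s in range(S):
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and mask[s, r, c] and mask[s, r2, c2]:
                    counts[quantized[s, r, c] - 1, quantized[s, r2, c2] - 1] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_features_oracle(p):
    """Literal formulas for the 12 statistics."""
    L = p.shape[0]
    out = {}
    out["AngScMom"] = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    out["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    mu = sum((i + 1) * p[i, j] for i in range(L) for j in range(L))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(L) for j in range(L))
    out["Correlat"] = (sum((i + 1) * (j + 1) * p[i, j] for i in range(L) for j in range(L))
                       - mu ** 2) / var if var > 0 else float("nan")
    out["SumOfSqs"] = var
    out["InvDfMom"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    psum = {k: 0.0 for k in range(2, 2 * L + 1)}
    pdiff = {k: 0.0 for k in range(L)}
    for i in range(L):
        for j in range(L):
            psum[i + j + 2] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    out["SumAverage"] = sum(k * v for k, v in psum.items())
    out["SumVarnc"] = sum((k - out["SumAverage"]) ** 2 * v for k, v in psum.items())
    out["SumEntrp"] = -sum(v * np.log(v) for v in psum.values() if v > 0)
    out["Entropy"] = -sum(p[i, j] * np.log(p[i, j])
                          for i in range(L) for j in range(L) if p[i, j] > 0)
    davg = sum(k * v for k, v in pdiff.items())
    out["DifVarnc"] = sum((k - davg) ** 2 * v for k, v in pdiff.items())
    out["DifEntrp"] = -sum(v * np.log(v) for v in pdiff.values() if v > 0)
    out["Dissim"] = sum(abs(i - j) * p[i, j] for i in range(L) for j in range(L))
    return out


def glrlm_oracle(quantized, mask, direction, n_levels):
    """Brute-force run scan along explicit line walks."""
    dr, dc = _DIRECTION_STEPS[direction]
    S, H, W = quantized.shape
    runs = {}
    for s in range(S):
        seen = set()
        for r0 in range(H):
            for c0 in range(W):
                # walk back to the line start
                r, c = r0, c0
                while 0 <= r - dr < H and 0 <= c - dc < W:
                    r, c = r - dr, c - dc
                if (r, c) in seen:
                    continue
                seen.add((r, c))
                # walk forward collecting runs
                level, length = 0, 0
                while 0 <= r < H and 0 <= c < W:
                    v = quantized[s, r, c] if mask[s, r, c] else 0
                    if v == level:
                        length += 1
                    else:
                        if level > 0:
                            runs[(level, length)] = runs.get((level, length), 0) + 1
                        level, length = v, 1
                    r, c = r + dr, c + dc
                if level > 0:
                    runs[(level, length)] = runs.get((level, length), 0) + 1
    max_len = max(H, W)
    out = np.zeros((n_levels, max_len))
    for (g, ln), n in runs.items():
        out[g - 1, ln - 1] = n
    return out


# ------------------------------------------------------------------- quantize

class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        voi = make_voi(np.full((2, 3, 3), -500.0))
        q = quantize(voi, 64)
        assert (q == 1).all()

    def test_two_values_two_levels(self):
        voi = make_voi([[[-800.0, -200.0], [-800.0, -200.0]]])
        q = quantize(voi, 2)
        assert set(q.ravel()) == {1, 2}

    def test_linear_ramp_gets_distinct_levels(self):
        ramp = np.arange(64, dtype=float).reshape(1, 8, 8)
        q = quantize(make_voi(ramp), 64)
        # direct binning oracle: floor((v - 0) / 63 * 64) + 1, clipped
        expected = np.clip(np.floor(ramp / 63.0 * 64).astype(int) + 1, 1, 64)
        assert (q == expected).all()
        assert len(set(q.ravel())) == 64

    def test_outside_mask_is_zero_and_errors(self, random_voi):
        q = quantize(random_voi, 16)
        assert (q[~random_voi.mask] == 0).all()
        empty = VOI(random_voi.intensities, np.zeros_like(random_voi.mask))
        with pytest.raises(DegenerateMaskError):
            quantize(empty, 16)
        with pytest.raises(ParameterError):
            quantize(random_voi, 1)


# ------------------------------------------------------------------ histogram

class TestHistogram:
    def test_constant_region(self):
        out = histogram_features(make_voi(np.full((2, 3, 3), -500.0)))
        assert out["Mean"] == -500.0
        assert out["Variance"] == 0.0
        assert all(out[f"Perc.{p}%"] == -500.0 for p in ("01", "10", "50", "90", "99"))
        assert np.isnan(out["Skewness"]) and np.isnan(out["Kurtosis"])

    def test_percentile_against_sort_interpolate_oracle(self):
        values = np.arange(1.0, 101.0)
        voi = make_voi(values.reshape(1, 10, 10))
        out = histogram_features(voi)
        # lower-percentile convention, linear interpolation between order stats:
        # position p/100*(n-1) in the sorted sample
        for name, p in (("Perc.01%", 1), ("Perc.10%", 10), ("Perc.50%", 50),
                        ("Perc.90%", 90), ("Perc.99%", 99)):
            pos = p / 100 * 99
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = values[lo] + (pos - lo) * (values[hi] - values[lo])
            assert out[name] == pytest.approx(expected)
        assert 10.0 <= out["Perc.10%"] <= 11.0

    def test_symmetric_values_have_zero_skewness(self):
        vals = np.array([-3.0, -1.0, 0.0, 1.0, 3.0, 0.0, 2.0, -2.0]).reshape(1, 2, 4)
        out = histogram_features(make_voi(vals))
        assert out["Skewness"] == pytest.approx(0.0, abs=1e-12)

    @given(arrays(float, (2, 4, 4), elements=st.floats(-1000, 1000)),
           st.floats(-200, 200))
    def test_shift_moves_mean_and_percentiles_not_variance(self, vals, c):
        base = histogram_features(make_voi(vals))
        shifted = histogram_features(make_voi(vals + c))
        assert shifted["Mean"] == pytest.approx(base["Mean"] + c, abs=1e-6)
        assert shifted["Perc.50%"] == pytest.approx(base["Perc.50%"] + c, abs=1e-6)
        assert shifted["Variance"] == pytest.approx(base["Variance"], rel=1e-9, abs=1e-6)


# ----------------------------------------------------------------------- GLCM

class TestGLCM:
    def test_toy_grid_pairs(self):
        q = np.array([[[1, 2], [1, 2]]])
        p = glcm(q, np.ones_like(q, bool), (0, 1), n_levels=2)
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5 and p[0, 0] == 0.0

    def test_constant_grid_single_entry(self):
        q = np.ones((1, 3, 3), dtype=int)
        p = glcm(q, np.ones_like(q, bool), (0, 1), n_levels=1)
        assert p[0, 0] == 1.0
        assert glcm_features(np.atleast_2d(p))["Contrast"] == 0.0

    def test_no_valid_pairs_raises(self):
        q = np.ones((1, 1, 1), dtype=int)
        with pytest.raises(EmptyMatrixError):
            glcm(q, np.ones_like(q, bool), (0, 1), n_levels=1)

    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (1, -1),
                                        (0, 3), (3, 3), (3, -3), (2, 0)])
    def test_matches_brute_force_on_random_grids(self, rng, offset):
        for _ in range(5):
            q = rng.integers(1, 7, (3, 6, 6))
            mask = rng.random((3, 6, 6)) > 0.25
            if not mask.any():
                continue
            try:
                p = glcm(q, mask, offset, n_levels=6)
            except EmptyMatrixError:
                continue
            expected = glcm_oracle(q, mask, offset, 6)
            np.testing.assert_allclose(p, expected, atol=1e-12)
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, p.T, atol=1e-15)

    def test_full_mask_matches_skimage(self, rng):
        """Independent library cross-check on an unmasked slice."""
        img = rng.integers(0, 6, (7, 7)).astype(np.uint8)
        ours = glcm(img[None] + 1, np.ones((1, 7, 7), bool), (0, 2), n_levels=6)
        ref = graycomatrix(img, distances=[2], angles=[0], levels=6,
                           symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_statistics_match_literal_formula_oracle(self, rng):
        q = rng.integers(1, 7, (3, 6, 6))
        mask = np.ones((3, 6, 6), bool)
        p = glcm(q, mask, (1, 1), n_levels=6)
        ours = glcm_features(p)
        expected = glcm_features_oracle(p)
        for name, v in expected.items():
            assert ours[name] == pytest.approx(v, abs=1e-10), name

    def test_sum_average_toy(self):
        q = np.array([[[1, 2], [1, 2]]])
        p = glcm(q, np.ones_like(q, bool), (0, 1), n_levels=2)
        assert glcm_features(p)["SumAverage"] == pytest.approx(3.0)

    def test_uniform_matrix_angular_second_moment(self):
        L = 4
        p = np.full((L, L), 1.0 / L ** 2)
        assert glcm_features(p)["AngScMom"] == pytest.approx(1.0 / L ** 2)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.ones((3, 3)))


# ---------------------------------------------------------------------- GLRLM

class TestGLRLM:
    def test_single_row_runs(self):
        q = np.array([[[1, 1, 2, 2, 2]]])
        r = glrlm(q, np.ones_like(q, bool), "0dgr", n_levels=2)
        assert r.sum() == 2
        assert r[0, 1] == 1 and r[1, 2] == 1
        assert glrlm_features(r)["GLevNonU"] == pytest.approx(1.0)

    def test_constant_row_single_run(self):
        q = np.ones((1, 1, 4), dtype=int)
        r = glrlm(q, np.ones_like(q, bool), "0dgr", n_levels=1)
        assert r[0, 3] == 1 and r.sum() == 1

    def test_same_gray_level_runs_give_gln_equal_r(self):
        # 3 separate runs of level 1 (broken by mask gaps)
        q = np.array([[[1, 0, 1, 0, 1]]]) + 0
        mask = q > 0
        q = np.where(mask, 1, 0)
        r = glrlm(q, mask, "0dgr", n_levels=1)
        R = r.sum()
        assert R == 3
        assert glrlm_features(r)["GLevNonU"] == pytest.approx(R)

    @pytest.mark.parametrize("direction", ["0dgr", "45dgr", "90dgr", "135dgr"])
    def test_matches_brute_force_and_conserves_voxels(self, rng, direction):
        for _ in range(5):
            q = rng.integers(1, 5, (3, 6, 6))
            mask = rng.random((3, 6, 6)) > 0.3
            if not mask.any():
                continue
            r = glrlm(q, mask, direction, n_levels=4)
            expected = glrlm_oracle(q, mask, direction, 4)
            np.testing.assert_array_equal(r, expected)
            lengths = np.arange(1, r.shape[1] + 1)
            assert (r.sum(axis=0) * lengths).sum() == mask.sum()

    def test_statistics_and_bounds(self, rng):
        q = rng.integers(1, 5, (2, 6, 6))
        mask = np.ones((2, 6, 6), bool)
        r = glrlm(q, mask, "0dgr", n_levels=4)
        feats = glrlm_features(r)
        assert 0 < feats["Fraction"] <= 1
        R = r.sum()
        g_sums = r.sum(axis=1)
        assert feats["GLevNonU"] == pytest.approx((g_sums ** 2).sum() / R)

    def test_pooled_matrix_sums_directions(self, rng):
        q = rng.integers(1, 5, (2, 5, 5))
        mask = np.ones((2, 5, 5), bool)
        mats = [glrlm(q, mask, d, n_levels=4) for d in _DIRECTION_STEPS]
        pooled = pooled_glrlm(mats)
        assert pooled.sum() == sum(m.sum() for m in mats)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyMatrixError):
            glrlm_features(np.zeros((3, 3)))


# --------------------------------------------------------------------- wavelet

class TestWavelet:
    def test_zero_voi_zero_energies(self):
        voi = make_voi(np.zeros((3, 40, 40)))
        out = wavelet_energies(voi)
        assert len(out) == 20
        assert all(v == 0.0 for v in out.values())

    def test_intensity_scaling_scales_energy_quadratically(self, random_voi):
        base = wavelet_energies(random_voi)
        scaled_voi = VOI(random_voi.intensities * 3.0, random_voi.mask)
        scaled = wavelet_energies(scaled_voi)
        for name, v in base.items():
            assert scaled[name] == pytest.approx(9.0 * v, rel=1e-9)

    def test_parseval_partition_per_level(self, rng):
        """Orthonormality: subband energies partition input energy exactly."""
        x = rng.standard_normal((64, 64))
        a = x
        for _ in range(5):
            a2, (h, v, d) = pywt.dwt2(a, "coif1", mode="periodization")
            total = sum((c ** 2).sum() for c in (a2, h, v, d))
            assert total == pytest.approx((a ** 2).sum(), rel=1e-10)
            a = a2

    def test_full_catalog_of_20_names(self, random_voi):
        out = wavelet_energies(random_voi)
        assert sorted(out) == sorted(
            f"WavEn{sb}_s-{s}" for sb in ("LL", "LH", "HL", "HH") for s in range(1, 6)
        )
        assert all(np.isfinite(v) and v >= 0 for v in out.values())


# ----------------------------------------------------------------------- shape

class TestShape:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        out = shape_features(mask, (1.0, 1.0, 1.0))
        assert out["Volume"] == 1.0
        assert out["Diameter3D"] == 0.0
        assert np.isnan(out["Sphericity"])

    def test_rod_longest_diameter_center_to_center(self):
        mask = np.zeros((1, 1, 10), bool)
        mask[0, 0, :] = True
        out = shape_features(mask, (1.0, 1.0, 1.0))
        assert out["Diameter3D"] == pytest.approx(9.0)

    def test_diameter_matches_brute_force_pairwise(self, rng):
        mask = rng.random((6, 6, 6)) > 0.6
        mask[0, 0, 0] = True  # non-empty
        spacing = (2.0, 1.0, 0.5)
        out = shape_features(mask, spacing)
        pts = np.argwhere(mask) * np.asarray(spacing)
        expected = max(
            np.linalg.norm(p - q) for p in pts for q in pts
        )
        assert out["Diameter3D"] == pytest.approx(expected)

    def test_digital_ball_sphericity(self, ball_voi):
        out = shape_features(ball_voi.mask, ball_voi.spacing)
        assert 0.9 <= out["Sphericity"] <= 1.0
        assert out["Compactness"] == pytest.approx(out["Sphericity"] ** 3, rel=1e-9)
        # ball is isotropic: elongation and flatness near 1
        assert out["Elongation"] > 0.95 and out["Flatness"] > 0.95

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.ones((2, 2, 2), bool)
        out = shape_features(mask, (2.0, 1.0, 0.5))
        assert out["Volume"] == pytest.approx(8 * 1.0)


# ----------------------------------------------------------------- extract_all

class TestExtractAll:
    def test_vector_has_full_catalog(self, random_voi):
        vec = extract_all(random_voi)
        assert len(vec) == 308
        assert list(vec.index) == catalog_names()
        groups = catalog_groups()
        counts = {}
        for n in vec.index:
            counts[groups[n]] = counts.get(groups[n], 0) + 1
        assert counts == {"shape": 8, "histogram": 9, "texture": 271, "wavelet": 20}

    def test_constant_voi_contrast_zero_nonuniformity_defined(self):
        img = np.full((4, 12, 12), -400.0)
        mask = np.zeros((4, 12, 12), bool)
        mask[1:3, 3:9, 3:9] = True
        vec = extract_all(VOI(img, mask))
        assert len(vec) == 308
        contrast = [n for n in vec.index if n.endswith("Contrast") or n.endswith("Dissim")]
        assert all(vec[n] == 0.0 for n in contrast)
        nonu = [n for n in vec.index if "GLevNonU" in n or "RLNonUni" in n]
        assert all(np.isfinite(vec[n]) for n in nonu)

    def test_deterministic(self, random_voi):
        v1 = extract_all(random_voi)
        v2 = extract_all(random_voi)
        assert (v1 == v2).all()

    def test_slice_permutation_invariance(self, rng):
        """Slice-aggregated texture is invariant to axial slice order."""
        img = rng.normal(-400, 100, (6, 12, 12))
        mask = np.zeros((6, 12, 12), bool)
        mask[:, 3:9, 3:9] = True
        voi = VOI(img, mask)
        perm = rng.permutation(6)
        voi_p = VOI(img[perm], mask[perm])
        v1, v2 = extract_all(voi), extract_all(voi_p)
        texture = [n for n, g in catalog_groups().items() if g == "texture"]
        np.testing.assert_allclose(v1[texture], v2[texture], rtol=1e-12)

    def test_intensity_shift_invariance_of_texture(self, random_voi):
        """Adding a constant changes mean/percentiles only; quantized texture
        and relative wavelet energies are unchanged."""
        shifted = VOI(random_voi.intensities + 150.0, random_voi.mask)
        v1, v2 = extract_all(random_voi), extract_all(shifted)
        assert v2["Mean"] == pytest.approx(v1["Mean"] + 150.0)
        assert v2["Perc.10%"] == pytest.approx(v1["Perc.10%"] + 150.0)
        assert v2["Variance"] == pytest.approx(v1["Variance"], rel=1e-9)
        texture = [n for n, g in catalog_groups().items() if g == "texture"]
        np.testing.assert_allclose(v1[texture], v2[texture], rtol=1e-9)
        # relative detail-band energies unchanged (LL absorbs the shift)
        detail = [n for n in v1.index if n.startswith(("WavEnLH", "WavEnHL", "WavEnHH"))]
        np.testing.assert_allclose(v1[detail], v2[detail], rtol=1e-6, atol=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            extract_all(VOI(np.zeros((2, 4, 4)), np.zeros((2, 4, 4), bool)))
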