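"""The 308-feature catalog: stable names, groups and ordering.

The catalog comprises 8 shape, 9 histogram, 271 texture (240 gray-level
co-occurrence + 31 run-length) and 20 wavelet-energy features.  Texture is
computed per axial slice with 2D offsets and MaZda-style names: ``S(d1,d2)``
identifies a co-occurrence offset of ``d1`` rows and ``d2`` columns,
``45dgr`` a run direction, ``WavEnLL_s-2`` the low-low wavelet subband
energy at decomposition scale 2.
"""

from __future__ import annotations

CATALOG_VERSION = "1.0"

SHAPE_FEATURES = (
    "Diameter3D",
    "Volume",
    "SurfaceArea",
    "Sphericity",
    "Compactness",
    "Elongation",
    "Flatness",
    "SurfVolRatio",
)

HISTOGRAM_FEATURES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc.01%",
    "Perc.10%",
    "Perc.50%",
    "Perc.90%",
    "Perc.99%",
)

GLCM_STATISTICS = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverage",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
    "Dissim",
)

#: Co-occurrence offsets (rows, columns) within an axial slice: four
#: directions at five inter-pixel distances.
GLCM_OFFSETS = tuple(
    (d1, d2)
    for d in range(1, 6)
    for (d1, d2) in ((0, d), (d, 0), (d, d), (d, -d))
)

GLRLM_STATISTICS = (
    "ShrtREmph",
    "LngREmph",
    "GLevNonU",
    "RLNonUni",
    "Fraction",
    "LowGREmph",
    "HighGREmph",
)

#: Run directions within an axial slice, by angle.
GLRLM_DIRECTIONS = ("0dgr", "45dgr", "90dgr", "135dgr")

#: Aggregates computed on runs pooled over the four directions.
GLRLM_POOLED = ("Pooled_GLevNonU", "Pooled_RLNonUni", "Pooled_Fraction")

WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")
WAVELET_SCALES = (1, 2, 3, 4, 5)


def glcm_feature_name(offset: tuple[int, int], stat: str) -> str:
    return f"S({offset[0]},{offset[1]}){stat}"


def glrlm_feature_name(direction: str, stat: str) -> str:
    return f"{direction}_{stat}"


def wavelet_feature_name(subband: str, scale: int) -> str:
    return f"WavEn{subband}_s-{scale}"


def glcm_feature_names() -> list[str]:
    return [glcm_feature_name(off, s) for off in GLCM_OFFSETS for s in GLCM_STATISTICS]


def glrlm_feature_names() -> list[str]:
    names = [glrlm_feature_name(d, s) for d in GLRLM_DIRECTIONS for s in GLRLM_STATISTICS]
    names.extend(GLRLM_POOLED)
    return names


def wavelet_feature_names() -> list[str]:
    return [wavelet_feature_name(sb, sc) for sc in WAVELET_SCALES for sb in WAVELET_SUBBANDS]


def texture_feature_names() -> list[str]:
    return glcm_feature_names() + glrlm_feature_names()


def catalog_names() -> list[str]:
    """All 308 feature names in canonical catalog order."""
    return (
        list(SHAPE_FEATURES)
        + list(HISTOGRAM_FEATURES)
        + texture_feature_names()
        + wavelet_feature_names()
    )


def catalog_groups() -> dict[str, str]:
    """Map feature name -> group ∈ {shape, histogram, texture, wavelet}."""
    groups: dict[str, str] = {}
    for n in SHAPE_FEATURES:
        groups[n] = "shape"
    for n in HISTOGRAM_FEATURES:
        groups[n] = "histogram"
    for n in texture_feature_names():
        groups[n] = "texture"
    for n in wavelet_feature_names():
        groups[n] = "wavelet"
    return groups
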