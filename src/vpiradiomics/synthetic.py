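"""Synthetic cohorts: feature tables, 3D nodule images, replicate pairs.

The study's CT scans are not public, so every downstream stage is exercised
on simulated inputs.  Three generators are provided:

* ``generate_feature_cohort`` draws a two-class cases×features table whose
  informative features follow the per-class Gaussian (mean, SD) parameters
  published for the five top-ranked signature features, plus uninformative
  noise features drawn identically in both classes.  Features are
  independent by default, with an optional within-class equicorrelation.
* ``generate_image_cohort`` builds 3D volumes containing an ellipsoidal
  nodule on a lung-density background, with a class-dependent intensity
  shift and texture correlation length (Gaussian-smoothed noise).
* ``perturb_segmentation`` emulates a second reader's segmentation by
  dilating/eroding the mask boundary and adding HU noise, yielding the
  replicate pairs used for reproducibility (CCC) filtering.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateMaskError, ParameterError
from .tables import COHORT_SIZES, SIGNATURE_FEATURE_PARAMS
from .voi import VOI


@dataclass
class FeatureCohortSpec:
    """Parameters of a simulated two-class feature table."""

    n_vpi_neg: int = COHORT_SIZES[0]
    n_vpi_pos: int = COHORT_SIZES[1]
    #: feature name -> ((mean−, sd−), (mean+, sd+))
    named_feature_params: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(SIGNATURE_FEATURE_PARAMS)
    )
    n_noise_features: int = 15
    noise_sd: float = 1.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_vpi_neg < 2 or self.n_vpi_pos < 2:
            raise ParameterError("need at least 2 cases per class")
        for name, ((m0, s0), (m1, s1)) in self.named_feature_params.items():
            if s0 <= 0 or s1 <= 0:
                raise ParameterError(f"non-positive SD for feature {name!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0.0 <= self.correlation < 1.0):
            raise ParameterError("correlation must be in [0, 1)")


def generate_feature_cohort(spec: FeatureCohortSpec) -> pd.DataFrame:
    """Simulate a labelled feature table (label 0 = VPI−, 1 = VPI+)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vpi_neg + spec.n_vpi_pos
    labels = np.concatenate(
        [np.zeros(spec.n_vpi_neg, dtype=int), np.ones(spec.n_vpi_pos, dtype=int)]
    )
    columns: dict[str, np.ndarray] = {"label": labels}

    named = list(spec.named_feature_params.items())
    z = rng.standard_normal((n, len(named)))
    if spec.correlation > 0 and len(named) > 1:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(spec.correlation) * shared + np.sqrt(1 - spec.correlation) * z
    for k, (name, (neg, pos)) in enumerate(named):
        mean = np.where(labels == 0, neg[0], pos[0])
        sd = np.where(labels == 0, neg[1], pos[1])
        columns[name] = mean + sd * z[:, k]
    for k in range(spec.n_noise_features):
        columns[f"Noise{k:03d}"] = spec.noise_sd * rng.standard_normal(n)

    table = pd.DataFrame(columns)
    table.index = pd.Index([f"case{k:04d}" for k in range(n)], name="case_id")
    return table


def replicate_feature_table(table: pd.DataFrame, noise_scale: float = 0.05,
                            seed: int = 0) -> pd.DataFrame:
    """A second-reader replicate of a feature table.

    Each feature column gets independent Gaussian measurement noise with SD
    ``noise_scale`` × the column's SD, emulating re-extraction after an
    independent segmentation.  The ``label`` column is untouched.
    """
    rng = np.random.default_rng(seed)
    rep = table.copy()
    for col in table.columns:
        if col == "label":
            continue
        sd = float(table[col].std(ddof=0))
        rep[col] = table[col] + noise_scale * sd * rng.standard_normal(len(table))
    return rep


@dataclass
class ImageCohortSpec:
    """Parameters of a simulated two-class 3D image cohort."""

    n_per_class: int = 25
    grid_shape: tuple[int, int, int] = (40, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nodule_radius_range: tuple[float, float] = (6.0, 10.0)  # mm
    class_intensity_shift: float = 150.0  # HU added to class 1 nodules
    #: texture correlation length (voxels of Gaussian smoothing) per class
    class_texture_scale: tuple[float, float] = (0.8, 2.0)
    background_hu: float = -800.0
    nodule_hu: float = -150.0
    texture_sd: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be positive")
        lo, hi = self.nodule_radius_range
        if not (0 < lo <= hi):
            raise ParameterError("invalid nodule_radius_range")
        half_extent = min(
            g * s / 2.0 for g, s in zip(self.grid_shape, self.spacing)
        )
        if hi >= half_extent - 1:
            raise ParameterError(
                f"nodule radius up to {hi} mm does not fit inside the grid "
                f"(half-extent {half_extent:.1f} mm)"
            )


def generate_image_cohort(spec: ImageCohortSpec) -> list[tuple[VOI, int]]:
    """Simulate ``2 × n_per_class`` nodule VOIs with balanced labels."""
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[VOI, int]] = []
    for label in (0, 1):
        for k in range(spec.n_per_class):
            voi = _simulate_nodule(spec, label, rng,
                                   case_id=f"img{label}{k:03d}")
            out.append((voi, label))
    return out


def _simulate_nodule(spec: ImageCohortSpec, label: int,
                     rng: np.random.Generator, case_id: str) -> VOI:
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing)
    lo, hi = spec.nodule_radius_range
    radius = rng.uniform(lo, hi)
    # jittered semi-axes give mild ellipsoids around the sampled radius
    semi = radius * rng.uniform(0.8, 1.2, size=3)
    center = (np.asarray(shape) - 1) / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    )
    rel = (coords - center) * spacing / semi
    mask = (rel ** 2).sum(axis=-1) <= 1.0

    base = np.full(shape, spec.background_hu)
    nodule_level = spec.nodule_hu + (spec.class_intensity_shift if label == 1 else 0.0)
    base[mask] = nodule_level
    sigma = spec.class_texture_scale[label]
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
        noise /= noise.std()
    intensities = base + spec.texture_sd * noise
    return VOI(intensities, mask, spacing=tuple(spec.spacing), case_id=case_id)


@dataclass
class PerturbationSpec:
    """A reader-replicate perturbation of an existing segmentation."""

    boundary_shift: int = 1  # voxels; >0 dilation, <0 erosion
    intensity_noise_sd: float = 10.0  # HU
    seed: int = 0

    def __post_init__(self):
        if self.intensity_noise_sd < 0:
            raise ParameterError("intensity_noise_sd must be >= 0")


def perturb_segmentation(voi: VOI, spec: PerturbationSpec) -> VOI:
    """Return a replicate VOI with a shifted mask boundary and HU noise."""
    if not voi.mask.any():
        raise DegenerateMaskError("cannot perturb an empty mask")
    mask = voi.mask
    if spec.boundary_shift > 0:
        mask = ndimage.binary_dilation(mask, iterations=spec.boundary_shift)
    elif spec.boundary_shift < 0:
        mask = ndimage.binary_erosion(mask, iterations=-spec.boundary_shift)
        if not mask.any():
            raise DegenerateMaskError(
                f"mask vanished after erosion by {-spec.boundary_shift} voxels"
            )
    rng = np.random.default_rng(spec.seed)
    intensities = voi.intensities
    if spec.intensity_noise_sd > 0:
        intensities = intensities + spec.intensity_noise_sd * rng.standard_normal(
            voi.intensities.shape
        )
    return VOI(intensities, mask, spacing=voi.spacing, case_id=voi.case_id)
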