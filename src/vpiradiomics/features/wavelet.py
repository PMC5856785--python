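"""Wavelet subband energies: WavEn{LL,LH,HL,HH}_s-{1..5}.

A 2D coiflet-1 discrete wavelet transform is applied per axial slice to the
mask bounding box.  Outside-mask voxels are filled with the in-mask mean and
the box is padded (with the same fill) to at least 32 pixels per in-plane
axis so that five decomposition scales are always available.  Periodized
boundary handling keeps the transform orthonormal, so subband energies
partition the input energy exactly at every scale.

The energy of a subband is the mean of its squared coefficients over the
coefficients whose support touches the mask (located by cascading the mask
through the same transform), averaged over slices that contain mask voxels.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..catalog import WAVELET_SCALES, wavelet_feature_name
from ..voi import VOI

_WAVELET = "coif1"
_MODE = "periodization"
_MIN_SIZE = 2 ** len(WAVELET_SCALES)


def wavelet_energies(voi: VOI, wavelet: str = _WAVELET) -> dict[str, float]:
    box = voi.bounding_box()
    img = voi.intensities[box].astype(float)
    msk = voi.mask[box]
    fill = float(img[msk].mean())
    img = np.where(msk, img, fill)
    img, msk = _pad(img, msk, fill)

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_slices = 0
    for s in range(img.shape[0]):
        if not msk[s].any():
            continue
        n_slices += 1
        a = img[s]
        support = msk[s].astype(float)
        for scale in WAVELET_SCALES:
            a, (h, v, d) = pywt.dwt2(a, wavelet, mode=_MODE)
            support = pywt.dwt2(support, wavelet, mode=_MODE)[0]
            supported = np.abs(support) > 1e-9
            if not supported.any():
                supported = np.ones_like(support, dtype=bool)
            for sb, coeffs in (("LL", a), ("LH", h), ("HL", v), ("HH", d)):
                name = wavelet_feature_name(sb, scale)
                sums[name] = sums.get(name, 0.0) + float(
                    (coeffs[supported] ** 2).mean()
                )
    return {k: v / n_slices for k, v in sums.items()}


def _pad(img: np.ndarray, msk: np.ndarray, fill: float):
    """Pad in-plane axes up to the minimum size, centring the box."""
    pads = [(0, 0)]
    for ax in (1, 2):
        short = max(0, _MIN_SIZE - img.shape[ax])
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        img = np.pad(img, pads, mode="constant", constant_values=fill)
        msk = np.pad(msk, pads, mode="constant", constant_values=False)
    return img, msk
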