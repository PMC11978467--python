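"""Minimal synthetic T1w-CE-like volume: an ellipsoidal enhancing lesion
inside a spherical "brain", with smooth random texture. Exists solely to
exercise the radiomic preprocessing/extraction stage; visual realism is a
non-goal.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .radiomics.preprocess import ImageVolume, MaskVolume


def generate_lesion_image(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    brain_radius_frac: float = 0.45,
    lesion_radii_mm: tuple[float, float, float] = (6.0, 5.0, 4.0),
    lesion_center_frac: tuple[float, float, float] = (0.5, 0.55, 0.45),
    brain_mean: float = 100.0,
    brain_sd: float = 10.0,
    lesion_contrast: float = 40.0,
    texture_sd: float = 15.0,
    texture_smoothing_vox: float = 1.5,
    seed: int = 0,
) -> tuple[ImageVolume, MaskVolume, MaskVolume]:
    """Return (image, lesion_mask, brain_mask) on a common grid."""
    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(float)
    phys = grid * np.asarray(spacing)[:, None, None, None]
    extent = np.asarray(shape) * np.asarray(spacing)
    center = extent / 2.0

    r2 = sum((phys[a] - center[a]) ** 2 for a in range(3))
    brain = r2 <= (brain_radius_frac * extent.min()) ** 2

    lc = extent * np.asarray(lesion_center_frac)
    lesion = (
        sum(((phys[a] - lc[a]) / lesion_radii_mm[a]) ** 2 for a in range(3)) <= 1.0
    )
    lesion &= brain
    if not lesion.any():
        raise ValueError("lesion placed outside the brain; adjust geometry")

    noise = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=shape), texture_smoothing_vox
    )
    noise *= texture_sd / max(noise.std(), 1e-12)
    img = np.full(shape, 20.0)  # background
    img[brain] = brain_mean + rng.normal(0.0, brain_sd, size=int(brain.sum()))
    img[lesion] = brain_mean + lesion_contrast + noise[lesion]

    return (
        ImageVolume(img, spacing),
        MaskVolume(lesion, spacing, role="lesion_gtv"),
        MaskVolume(brain, spacing, role="brain"),
    )
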