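"""Image-domain preprocessing: isotropic resampling and brain-masked z-scoring.

Arrays follow the (slice, row, column) axis convention of
``SimpleITK.GetArrayFromImage``; ``spacing`` is stored in the same axis order
(mm per array axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk


@dataclass
class ImageVolume:
    """A 3D scalar volume with voxel spacing in mm (array-axis order)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("expected a 3D volume")
        if self.data.size == 0:
            raise ValueError("empty image")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")


@dataclass
class MaskVolume:
    """Binary mask on the same grid as its paired image."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    role: str = "lesion_gtv"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("expected a 3D mask")
        if self.role == "lesion_gtv" and not self.data.any():
            raise ValueError("lesion mask is empty")


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing(tuple(reversed(spacing)))  # sitk uses (x, y, z)
    img.SetOrigin(tuple(reversed(origin)))
    return img


def _resample_one(
    data: np.ndarray, spacing, origin, target_mm: float, interpolator
) -> np.ndarray:
    img = _to_sitk(data.astype(np.float32), spacing, origin)
    in_size = np.array(img.GetSize(), dtype=float)
    in_spacing = np.array(img.GetSpacing(), dtype=float)
    out_size = [int(np.round(n * s / target_mm)) for n, s in zip(in_size, in_spacing)]
    res = sitk.Resample(
        img,
        out_size,
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        (target_mm,) * 3,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat32,
        # the output grid can extend half a voxel past the last input center;
        # clamp to the nearest edge voxel instead of zero-filling
        useNearestNeighborExtrapolator=True,
    )
    return sitk.GetArrayFromImage(res)


def resample_isotropic(
    image: ImageVolume,
    masks: dict[str, MaskVolume] | None = None,
    target_mm: float = 0.5,
) -> tuple[ImageVolume, dict[str, MaskVolume]]:
    """Resample image (linear) and masks (nearest-neighbor) to an isotropic grid.

    Inputs already at the target spacing pass through with identical values.
    """
    masks = masks or {}
    if all(abs(s - target_mm) < 1e-9 for s in image.spacing):
        return (
            ImageVolume(image.data.copy(), image.spacing, image.origin),
            {
                k: MaskVolume(m.data.copy(), m.spacing, m.role, m.origin)
                for k, m in masks.items()
            },
        )
    out_img = _resample_one(
        image.data, image.spacing, image.origin, target_mm, sitk.sitkLinear
    )
    new_spacing = (target_mm,) * 3
    out_masks = {}
    for key, m in masks.items():
        if m.data.shape != image.data.shape:
            raise ValueError(f"mask {key!r} is not on the image grid")
        arr = _resample_one(
            m.data.astype(np.uint8), m.spacing, m.origin, target_mm, sitk.sitkNearestNeighbor
        )
        out_masks[key] = MaskVolume(arr > 0.5, new_spacing, m.role, m.origin)
    return ImageVolume(out_img, new_spacing, image.origin), out_masks


def normalize_zscore(
    image: ImageVolume,
    brain_mask: MaskVolume,
    lesion_mask: MaskVolume | None = None,
    clip_sd: float = 3.0,
) -> ImageVolume:
    """Z-score using brain voxels excluding the lesion; clip to +/- clip_sd.

    The lesion is excluded from the mean/SD so the lesion's own enhancement
    cannot shift the normalization; clipping standardizes the intensity range
    without changing ranks inside the clip band.
    """
    ref = brain_mask.data.copy()
    if lesion_mask is not None:
        ref &= ~lesion_mask.data
    if not ref.any():
        raise ValueError("brain mask minus lesion mask is empty")
    vals = image.data[ref].astype(float)
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero variance in reference region")
    z = (image.data.astype(float) - mu) / sd
    np.clip(z, -clip_sd, clip_sd, out=z)
    return ImageVolume(z, image.spacing, image.origin)


def read_nifti_image(path: str) -> ImageVolume:
    img = sitk.ReadImage(str(path))
    return ImageVolume(
        sitk.GetArrayFromImage(img).astype(float),
        tuple(reversed(img.GetSpacing())),
        tuple(reversed(img.GetOrigin())),
    )


def read_nifti_mask(path: str, role: str = "lesion_gtv") -> MaskVolume:
    img = sitk.ReadImage(str(path))
    return MaskVolume(
        sitk.GetArrayFromImage(img) > 0.5,
        tuple(reversed(img.GetSpacing())),
        role,
        tuple(reversed(img.GetOrigin())),
    )


def write_nifti(volume: ImageVolume | MaskVolume, path: str) -> None:
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    sitk.WriteImage(_to_sitk(data, volume.spacing, volume.origin), str(path))
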