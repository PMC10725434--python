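"""NIfTI I/O, isotropic cubic-spline resampling, and intensity z-scoring."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
from scipy import ndimage

from .types import VolumeImage

#: production grid after 1.5 mm resampling
DEFAULT_SHAPE = (105, 127, 105)
DEFAULT_SPACING = 1.5


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read a 3D NIfTI-1 image (optionally gzipped) into a VolumeImage."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got {data.ndim}D with shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeImage(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def write_volume(vol: VolumeImage, path: str | os.PathLike) -> None:
    """Write a VolumeImage as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def resample_isotropic(
    vol: VolumeImage,
    target_spacing: float = DEFAULT_SPACING,
    output_shape: tuple[int, int, int] | None = None,
) -> VolumeImage:
    """Resample to an isotropic grid with cubic spline interpolation.

    Output voxel ``j`` along axis ``a`` samples the input at continuous
    index ``j * target_spacing / spacing[a]`` (grids share the corner
    voxel centre), so coincident grid points reproduce input values
    exactly. When ``output_shape`` is omitted the grid covers
    ``floor(extent_mm / target_spacing)`` voxels per axis.
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    if output_shape is None:
        output_shape = tuple(
            int(np.floor(n * s / target_spacing))
            for n, s in zip(vol.shape, vol.spacing)
        )
    output_shape = tuple(int(n) for n in output_shape)
    if any(n < 1 for n in output_shape):
        raise ValueError(f"degenerate output shape {output_shape}")

    scale = [target_spacing / s for s in vol.spacing]
    axes = [np.arange(n) * sc for n, sc in zip(output_shape, scale)]
    coords = np.meshgrid(*axes, indexing="ij")
    data = ndimage.map_coordinates(
        vol.data, np.stack(coords), order=3, mode="nearest"
    )
    return VolumeImage(
        data=data, spacing=(target_spacing,) * 3, origin=vol.origin
    )


def normalize_intensity(vol: VolumeImage) -> VolumeImage:
    """Z-score foreground (nonzero) voxels; background stays exactly zero.

    Idempotent: re-applying to an already normalized volume changes
    nothing beyond float rounding, because the foreground mask (nonzero
    voxels) is preserved and already has mean 0, sd 1.
    """
    data = vol.data
    fg = data != 0
    if not fg.any():
        raise ValueError("volume has no nonzero voxels to normalize")
    mu = data[fg].mean()
    sd = data[fg].std()
    if sd == 0:
        raise ValueError("zero intensity variance over foreground; cannot z-score")
    out = np.zeros_like(data, dtype=np.float64)
    out[fg] = (data[fg] - mu) / sd
    return VolumeImage(data=out, spacing=vol.spacing, origin=vol.origin)
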