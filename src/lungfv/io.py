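"""NIfTI input/output and mask resampling.

Volumes and masks travel as NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel.
Scalar volumes are stored as float64 so a write/read round trip is
bit-exact; masks as unsigned 8-bit 0/1. Activity volumes have negative
reconstructed values clamped to zero at ingest (count logged) so that
cumulative-count fractions are well defined.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageGrid, LungFVError, ScalarVolume

__all__ = ["read_volume", "read_mask", "write_volume", "write_mask", "resample_mask"]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _grid_from_nifti(img: nib.Nifti1Image) -> ImageGrid:
    aff = np.asarray(img.affine, dtype=float)
    # axis-aligned check: each voxel axis maps to exactly one world axis
    for i in range(3):
        col = aff[:3, i]
        dominant = np.max(np.abs(col))
        if dominant <= 0 or np.sum(np.abs(col) > 1e-3 * dominant) != 1:
            raise LungFVError(
                "oblique NIfTI affine not supported: voxel axis "
                f"{i} maps to multiple world axes ({col})"
            )
    orientation = "".join(nib.aff2axcodes(aff))
    spacing = tuple(float(np.max(np.abs(aff[:3, i]))) for i in range(3))
    origin = tuple(float(x) for x in aff[:3, 3])
    shape = tuple(int(s) for s in img.shape[:3])
    return ImageGrid(shape, spacing, origin, orientation)


def _load_payload(path: PathLike) -> tuple[nib.Nifti1Image, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise LungFVError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as e:
        raise LungFVError(f"{path}: cannot read as NIfTI ({e})") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise LungFVError(f"{path}: expected a 3D image, got shape {data.shape}")
    return img, np.asarray(data)


def read_volume(path: PathLike, expected_modality: str) -> ScalarVolume:
    """Read a NIfTI scalar volume.

    ``expected_modality`` is ``"CT-HU"`` or ``"activity"``. Activity volumes
    must be finite everywhere; negative values are clamped to zero with the
    clamp count logged and recorded on the returned volume.
    """
    img, data = _load_payload(path)
    data = data.astype(np.float64)
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise LungFVError(f"{path}: {n_bad} non-finite voxel(s) (NaN/Inf)")
    n_clamped = 0
    if expected_modality == "activity":
        neg = data < 0
        n_clamped = int(neg.sum())
        if n_clamped:
            log.info("%s: clamped %d negative activity voxel(s) to 0", path, n_clamped)
            data = np.where(neg, 0.0, data)
    return ScalarVolume(_grid_from_nifti(img), data, expected_modality, n_clamped=n_clamped)


def read_mask(path: PathLike) -> BinaryMask:
    """Read a NIfTI binary mask (any nonzero voxel counts as inside)."""
    img, data = _load_payload(path)
    return BinaryMask(_grid_from_nifti(img), data != 0)


def write_volume(vol: ScalarVolume, path: PathLike) -> None:
    """Write a scalar volume as float64 NIfTI (bit-exact round trip)."""
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: PathLike) -> None:
    """Write a binary mask as uint8 0/1 NIfTI carrying the mask's geometry."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def resample_mask(mask: BinaryMask, target: ImageGrid) -> BinaryMask:
    """Nearest-neighbour resample a mask onto ``target`` in world coordinates.

    Needed because the anatomical lung volume is contoured on the CT grid but
    all counting happens in PET voxels. Nearest neighbour keeps the mask
    binary. Source and target must overlap in physical space.
    """
    if mask.grid.matches(target):
        return BinaryMask(target, mask.values.copy())

    ext_s = mask.grid.physical_extent()
    ext_t = target.physical_extent()
    half_s = np.array(mask.grid.spacing_mm) / 2.0
    half_t = np.array(target.spacing_mm) / 2.0
    # extents measured between outer voxel faces
    if np.any(ext_s[:, 1] + half_s.max() < ext_t[:, 0] - half_t.max()) or np.any(
        ext_t[:, 1] + half_t.max() < ext_s[:, 0] - half_s.max()
    ):
        raise LungFVError("resample_mask: source and target grids are physically disjoint")

    m = np.linalg.inv(mask.grid.affine) @ target.affine
    out = ndimage.affine_transform(
        mask.values.astype(np.uint8),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(target, out.astype(bool))
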