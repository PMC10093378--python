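"""Whole-lung anatomical volume (AV) segmentation from CT.

The AV is the reference region for every functional-volume percentage. It is
contoured automatically on the CT by Hounsfield-unit rules: aerated lung sits
around -800 HU, soft tissue around 0 HU, and exterior air at -1000 HU. The
pipeline is the standard lung-CT heuristic:

1. keep voxels with ``hu_lower < HU < hu_upper``;
2. drop connected components touching the image boundary (exterior air);
3. keep the ``keep_components`` largest remaining components, each at least
   ``min_component_ml``;
4. morphological closing with a ball of ``closing_radius_mm`` to reabsorb
   intra-lung vessels.

Manual review is replaced by logged component statistics plus an override
path: every downstream operation also accepts a user-supplied mask. The AV is
purely HU-defined — lesions, effusions and central airways are not treated
specially (trachea/main bronchi typically merge into boundary-connected or
sub-threshold components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, LungFVError, ScalarVolume

__all__ = ["AVParams", "segment_lung_av", "av_stats", "NoLungFoundError"]

log = logging.getLogger(__name__)


class NoLungFoundError(LungFVError):
    pass


@dataclass(frozen=True)
class AVParams:
    """Parameters of the HU-rule lung segmentation.

    Defaults are standard lung-CT heuristics: a (-1024, -300) HU window,
    the two largest non-boundary components of at least 100 ml, and a 3 mm
    closing radius.
    """

    hu_upper: float = -300.0
    hu_lower: float = -1024.0
    min_component_ml: float = 100.0
    closing_radius_mm: float = 3.0
    keep_components: int = 2

    def __post_init__(self):
        if self.hu_lower >= self.hu_upper:
            raise ValueError("hu_lower must be < hu_upper")
        if self.min_component_ml <= 0:
            raise ValueError("min_component_ml must be > 0")
        if self.keep_components < 1:
            raise ValueError("keep_components must be >= 1")
        if self.closing_radius_mm < 0:
            raise ValueError("closing_radius_mm must be >= 0")


def _ball_footprint(radius_mm: float, spacing_mm: Tuple[float, float, float]) -> np.ndarray | None:
    """Anisotropy-aware ball structuring element; None if it degenerates to a point."""
    r = np.maximum(np.floor(radius_mm / np.asarray(spacing_mm)).astype(int), 0)
    if not r.any():
        return None
    grids = np.ogrid[tuple(slice(-n, n + 1) for n in r)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing_mm))
    return dist2 <= radius_mm**2


def segment_lung_av(ct: ScalarVolume, params: AVParams = AVParams()) -> BinaryMask:
    """Segment the whole-lung anatomical volume from a CT-HU volume.

    Raises :class:`NoLungFoundError` if no component survives the size filter.
    """
    if ct.modality != "CT-HU":
        raise LungFVError(f"segment_lung_av expects a CT-HU volume, got {ct.modality!r}")
    hu = ct.values
    cand = (hu > params.hu_lower) & (hu < params.hu_upper)

    labels, n = ndimage.label(cand)
    if n == 0:
        raise NoLungFoundError("no lung-like region found (no voxels in HU window)")

    # components touching the image boundary are exterior air
    boundary_labels = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=ax)
            boundary_labels.update(np.unique(face[face > 0]).tolist())

    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index=np.arange(1, n + 1))
    vox_ml = ct.grid.voxel_volume_ml
    candidates = [
        (int(sz), lab)
        for lab, sz in zip(range(1, n + 1), sizes)
        if lab not in boundary_labels and sz * vox_ml >= params.min_component_ml
    ]
    if not candidates:
        raise NoLungFoundError("no lung-like region found")

    candidates.sort(reverse=True)
    kept = candidates[: params.keep_components]
    log.info(
        "lung segmentation: %d candidate component(s), kept %d with volumes %s ml",
        len(candidates),
        len(kept),
        [round(sz * vox_ml, 1) for sz, _ in kept],
    )
    mask = np.isin(labels, [lab for _, lab in kept])

    foot = _ball_footprint(params.closing_radius_mm, ct.grid.spacing_mm)
    if foot is not None:
        mask = ndimage.binary_closing(mask, structure=foot)
    return BinaryMask(ct.grid, mask)


def av_stats(av: BinaryMask) -> Tuple[int, float]:
    """Return ``(voxel_count, volume_ml)`` of a mask."""
    return av.voxel_count, av.volume_ml
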