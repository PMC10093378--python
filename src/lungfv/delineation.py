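"""Functional-volume delineation on perfusion PET within a lung mask.

Two threshold families are implemented.

**pmax method** (the classic approach): fix a threshold at X% of the maximum
voxel intensity within the anatomical volume (AV) and keep AV voxels whose
value is *strictly higher* than that threshold. Its reference — the hottest
single voxel — is fragile: noise or a focal hot spot moves every volume.

**WLF method** (whole-lung-function): the FV-X% volume is the *minimal*
volume containing X% of the total counts in the AV,

    FV = (counts inside the segmented volume) / (counts in the AV).

It is realized by scanning pmax thresholds from 95% down to 5% in 0.1%
steps and selecting the largest (first satisfying) threshold whose FV
reaches the target — the unique rule consistent with minimality at the
scan's granularity. ``wlf_delineate_iterative`` implements that scan with a
single descending sort plus cumulative sums evaluated at all scan
thresholds (mathematically identical to running every segmentation
independently; ``literal=True`` does exactly that, for conformance
checking). ``wlf_delineate_exact`` is an independent oracle that sorts AV
voxels by value and accumulates whole tie-groups until the target counts
fraction is reached — the definition itself, with no threshold grid.

All percentages are voxel-count ratios (volume) and value-sum ratios
(activity) within one grid, so voxel-volume factors cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .core import BinaryMask, LungFVError, ScalarVolume, assert_same_grid

__all__ = [
    "ThresholdSegmentation",
    "FunctionalVolumeResult",
    "WLFParams",
    "pmax_value",
    "threshold_segment",
    "pmax_series",
    "fv_of_mask",
    "wlf_delineate_iterative",
    "wlf_delineate_exact",
    "complement_mask",
    "PRESET_TARGETS",
    "DEFAULT_PMAX_PCTS",
]

log = logging.getLogger(__name__)

DEFAULT_PMAX_PCTS = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

#: named functional-volume presets: highly functional lung, intermediate,
#: and the poorly-functional region taken as AV minus the FV90% volume
PRESET_TARGETS = {
    "highly_functional": 50.0,
    "intermediate": 70.0,
    "poorly_functional_complement": 90.0,
}

# slack on FV >= target comparisons, absorbing float summation error only
_FV_TOL = 1e-9


@dataclass
class ThresholdSegmentation:
    """One pmax-threshold segmentation with its volume/activity metrics."""

    threshold_pct_pmax: float
    absolute_threshold: float
    mask: BinaryMask
    volume_pct_av: float
    activity_pct_total: float
    volume_ml: float


@dataclass
class FunctionalVolumeResult:
    """One WLF target's result.

    ``boundary_flag`` is True when even the lowest scanned threshold could
    not reach the target counts fraction (the scan is then not extended, to
    stay faithful to the published 5–95% range).
    """

    target_fv_pct: float
    achieved_fv_pct: float
    threshold_pct_pmax: float
    mask: BinaryMask
    volume_pct_av: float
    volume_ml: float
    boundary_flag: bool = False


@dataclass(frozen=True)
class WLFParams:
    """Scan range/step and FV targets for the iterative WLF method."""

    scan_lo_pct: float = 5.0
    scan_hi_pct: float = 95.0
    step_pct: float = 0.1
    targets: Sequence[float] = tuple(float(x) for x in range(10, 100, 10))

    def __post_init__(self):
        if not (0 < self.scan_lo_pct < self.scan_hi_pct <= 100):
            raise ValueError("need 0 < scan_lo_pct < scan_hi_pct <= 100")
        if self.step_pct <= 0:
            raise ValueError("step_pct must be > 0")
        if any(not (0 < t < 100) for t in self.targets):
            raise ValueError("targets must lie in (0, 100)")

    def thresholds(self) -> np.ndarray:
        """Scanned %pmax thresholds, descending from hi to lo."""
        n = int(round((self.scan_hi_pct - self.scan_lo_pct) / self.step_pct))
        return self.scan_hi_pct - np.arange(n + 1) * self.step_pct


def _av_activity(pet: ScalarVolume, av: BinaryMask) -> np.ndarray:
    assert_same_grid(pet, av)
    if pet.modality != "activity":
        raise LungFVError(f"expected an activity volume, got {pet.modality!r}")
    if av.voxel_count == 0:
        raise LungFVError("empty AV mask")
    vals = pet.values[av.values]
    if not (vals > 0).any():
        raise LungFVError("no activity in AV")
    return vals


def pmax_value(pet: ScalarVolume, av: BinaryMask) -> float:
    """Maximum activity over AV voxels (the pmax reference value)."""
    return float(_av_activity(pet, av).max())


def threshold_segment(pet: ScalarVolume, av: BinaryMask, threshold_pct_pmax: float) -> ThresholdSegmentation:
    """Segment AV voxels with activity strictly above X% of pmax."""
    if not (0 < threshold_pct_pmax <= 100):
        raise LungFVError("threshold_pct_pmax must be in (0, 100]")
    vals = _av_activity(pet, av)
    pmax = float(vals.max())
    thr = pmax * threshold_pct_pmax / 100.0
    inside = av.values & (pet.values > thr)
    mask = BinaryMask(av.grid, inside)
    n_av = av.voxel_count
    total = float(vals.sum())
    return ThresholdSegmentation(
        threshold_pct_pmax=float(threshold_pct_pmax),
        absolute_threshold=thr,
        mask=mask,
        volume_pct_av=100.0 * mask.voxel_count / n_av,
        activity_pct_total=100.0 * float(pet.values[inside].sum()) / total,
        volume_ml=mask.volume_ml,
    )


def pmax_series(
    pet: ScalarVolume, av: BinaryMask, pct_list: Sequence[float] = DEFAULT_PMAX_PCTS
) -> List[ThresholdSegmentation]:
    """One :func:`threshold_segment` per percentage, in input order."""
    return [threshold_segment(pet, av, pct) for pct in pct_list]


def fv_of_mask(pet: ScalarVolume, av: BinaryMask, mask: BinaryMask) -> float:
    """Counts fraction (percent) of ``mask`` relative to total AV counts."""
    vals = _av_activity(pet, av)
    if not mask.is_subset_of(av):
        raise LungFVError("mask is not contained in the AV")
    return 100.0 * float(pet.values[mask.values].sum()) / float(vals.sum())


def wlf_delineate_iterative(
    pet: ScalarVolume,
    av: BinaryMask,
    params: WLFParams = WLFParams(),
    literal: bool = False,
) -> List[FunctionalVolumeResult]:
    """WLF delineation by the iterative threshold scan.

    For each target X the scan runs downward from ``scan_hi_pct`` in
    ``step_pct`` steps and selects the first (largest) threshold whose FV
    reaches X. If even ``scan_lo_pct`` falls short the boundary segmentation
    is returned with ``boundary_flag`` set and a warning logged.

    ``literal=True`` performs every scanned segmentation as an independent
    :func:`threshold_segment` call (slow; for conformance testing). The
    default path evaluates the identical quantities from one descending sort
    and cumulative sums.
    """
    thresholds = params.thresholds()
    if literal:
        return _wlf_literal(pet, av, params, thresholds)

    vals = _av_activity(pet, av)
    pmax = float(vals.max())
    total = float(vals.sum())
    asc = np.sort(vals)                      # ascending
    cum_desc = np.concatenate([[0.0], np.cumsum(asc[::-1])])
    n = asc.size
    abs_thr = pmax * thresholds / 100.0
    # k[i] = number of AV voxels strictly above abs_thr[i]
    k = n - np.searchsorted(asc, abs_thr, side="right")
    fv = 100.0 * cum_desc[k] / total         # non-decreasing along the scan

    results: List[FunctionalVolumeResult] = []
    for target in params.targets:
        hit = np.nonzero(fv >= target - _FV_TOL)[0]
        if hit.size:
            idx, boundary = int(hit[0]), False
        else:
            idx, boundary = len(thresholds) - 1, True
            log.warning(
                "WLF target %.1f%% not reachable at scan_lo=%.1f%%pmax "
                "(FV there = %.2f%%); returning boundary segmentation",
                target, params.scan_lo_pct, fv[-1],
            )
        seg = threshold_segment(pet, av, float(thresholds[idx]))
        results.append(
            FunctionalVolumeResult(
                target_fv_pct=float(target),
                achieved_fv_pct=seg.activity_pct_total,
                threshold_pct_pmax=seg.threshold_pct_pmax,
                mask=seg.mask,
                volume_pct_av=seg.volume_pct_av,
                volume_ml=seg.volume_ml,
                boundary_flag=boundary,
            )
        )
    return results


def _wlf_literal(pet, av, params, thresholds) -> List[FunctionalVolumeResult]:
    results = []
    for target in params.targets:
        chosen: Optional[ThresholdSegmentation] = None
        boundary = False
        for t in thresholds:
            seg = threshold_segment(pet, av, float(t))
            if seg.activity_pct_total >= target - _FV_TOL:
                chosen = seg
                break
        if chosen is None:
            chosen = threshold_segment(pet, av, float(thresholds[-1]))
            boundary = True
        results.append(
            FunctionalVolumeResult(
                target_fv_pct=float(target),
                achieved_fv_pct=chosen.activity_pct_total,
                threshold_pct_pmax=chosen.threshold_pct_pmax,
                mask=chosen.mask,
                volume_pct_av=chosen.volume_pct_av,
                volume_ml=chosen.volume_ml,
                boundary_flag=boundary,
            )
        )
    return results


def wlf_delineate_exact(
    pet: ScalarVolume, av: BinaryMask, targets: Sequence[float] = WLFParams().targets
) -> List[FunctionalVolumeResult]:
    """Exact minimal-volume delineation by descending sort over tie-groups.

    AV voxel values are sorted descending and accumulated in whole
    tie-groups (equal-valued voxels are indivisible by any threshold); for
    each target the mask is the shortest tie-group-closed prefix whose
    counts reach the target. The reported threshold is the largest excluded
    value as a percentage of pmax (0 when nothing is excluded), so the mask
    is exactly the strict-threshold segmentation at that value.
    """
    vals = _av_activity(pet, av)
    if any(not (0 < t < 100) for t in targets):
        raise LungFVError("targets must lie in (0, 100)")
    pmax = float(vals.max())
    total = float(vals.sum())
    n = vals.size
    uniq, counts = np.unique(vals, return_counts=True)       # ascending
    uniq, counts = uniq[::-1], counts[::-1]                  # descending
    cum_counts = np.cumsum(uniq * counts)
    cum_voxels = np.cumsum(counts)

    results = []
    for target in targets:
        need = target / 100.0 * total
        g = int(np.searchsorted(cum_counts, need - abs(need) * 1e-12, side="left"))
        g = min(g, len(uniq) - 1)
        if g + 1 < len(uniq):
            excluded = float(uniq[g + 1])
            inside = av.values & (pet.values > excluded)
            thr_pct = 100.0 * excluded / pmax
        else:
            inside = av.values.copy()
            thr_pct = 0.0
        mask = BinaryMask(av.grid, inside)
        results.append(
            FunctionalVolumeResult(
                target_fv_pct=float(target),
                achieved_fv_pct=100.0 * float(cum_counts[g]) / total,
                threshold_pct_pmax=thr_pct,
                mask=mask,
                volume_pct_av=100.0 * float(cum_voxels[g]) / n,
                volume_ml=mask.volume_ml,
                boundary_flag=False,
            )
        )
    return results


def complement_mask(av: BinaryMask, mask: BinaryMask) -> BinaryMask:
    """AV minus ``mask`` — e.g. the poorly functional lung outside FV90%."""
    if not mask.is_subset_of(av):
        raise LungFVError("mask is not contained in the AV")
    return BinaryMask(av.grid, av.values & ~mask.values)
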