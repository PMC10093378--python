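"""Synthetic perfusion PET/CT phantoms with analytic ground truth.

Each phantom is a CT volume (exterior air, soft-tissue body, two aerated
lung ellipsoids) plus a co-registered activity volume carrying one of the
supported perfusion patterns inside the lungs and zero outside. Every
pattern has a closed-form cumulative activity–volume curve F(v) — the
counts fraction contained in the hottest volume fraction v — so threshold
delineations can be checked against known truth:

* ``Uniform``: F(v) = v.
* ``LinearGradient``: activity constant within each slice along one grid
  axis, rising linearly from 1 to ``ratio`` across the lungs; F is built
  from per-slice voxel counts, piecewise linear, concave.
* ``TwoCompartment(v, f)``: a compact sub-region holding volume fraction v
  of the lungs carries counts fraction f (v < f: the small compartment is
  hotter); F interpolates (0,0) → (v, f) → (1,1).
* ``Defect(w, scale)``: a compact sub-region of volume fraction w has its
  activity multiplied by ``scale`` < 1 (a perfusion defect).

Hot spots — focal, artefactually intense accumulations such as clumped
macroaggregated albumin — can be injected as single voxels carrying either
a stated fraction of total counts or a stated multiple of the current
maximum. A multiplicative tie-breaking jitter (default relative 1e-6) is
applied to all activity values: reconstructed PET values are continuous, so
exact ties are measure-zero in practice, and piecewise-constant idealized
patterns would otherwise form voxel tie-groups no intensity threshold can
split. Optional multiplicative Gaussian noise (standard deviation
proportional to local activity) emulates post-reconstruction image noise,
whose magnitude grows with local signal; raw Poisson counting is not
simulated.

Geometry defaults sit on a 64x64x64 grid at 4 mm isotropic spacing —
the reconstruction scale of clinical perfusion PET — giving two lungs of
roughly 0.5-0.6 l each (~17k lung voxels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageGrid, LungFVError, ScalarVolume
from .metrics import classify_pft

__all__ = [
    "Ellipsoid",
    "Uniform",
    "LinearGradient",
    "TwoCompartment",
    "Defect",
    "Hotspot",
    "PhantomSpec",
    "PhantomTruth",
    "FVCurve",
    "default_grid",
    "generate_phantom",
    "inject_hotspot",
    "generate_cohort",
    "CohortStudy",
]

log = logging.getLogger(__name__)


def default_grid(n: int = 64, spacing: float = 4.0) -> ImageGrid:
    """Isotropic grid centered on the world origin."""
    origin = -(n - 1) * spacing / 2.0
    return ImageGrid((n, n, n), (spacing,) * 3, (origin,) * 3, "RAS")


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: Tuple[float, float, float]
    semi_axes_mm: Tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be > 0")

    def contains(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes_mm)) / 1000.0


# ---------------------------------------------------------------------------
# activity patterns


@dataclass(frozen=True)
class Uniform:
    pass


@dataclass(frozen=True)
class LinearGradient:
    axis: int = 2
    ratio: float = 3.0

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.ratio <= 1:
            raise ValueError("ratio must be > 1")


@dataclass(frozen=True)
class TwoCompartment:
    volume_fraction: float = 0.2
    counts_fraction: float = 0.6

    def __post_init__(self):
        v, f = self.volume_fraction, self.counts_fraction
        if not (0 < v < 1):
            raise ValueError("volume_fraction must be in (0, 1)")
        if not (v < f < 1):
            raise ValueError("counts_fraction must satisfy v < f < 1 (small compartment hotter)")


@dataclass(frozen=True)
class Defect:
    volume_fraction: float = 0.15
    scale: float = 0.2

    def __post_init__(self):
        if not (0 < self.volume_fraction < 1):
            raise ValueError("volume_fraction must be in (0, 1)")
        if not (0 < self.scale < 1):
            raise ValueError("scale must be in (0, 1)")


Pattern = Union[Uniform, LinearGradient, TwoCompartment, Defect]


@dataclass(frozen=True)
class Hotspot:
    """A single-voxel focal accumulation.

    Exactly one of ``counts_fraction`` (the voxel carries this fraction of
    the *new* total) or ``multiple_of_pmax`` (the voxel is set to this
    multiple of the current maximum) must be given. ``location_mm`` picks
    the nearest lung voxel; None picks a seeded random lung voxel.
    """

    counts_fraction: Optional[float] = None
    multiple_of_pmax: Optional[float] = None
    location_mm: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        if (self.counts_fraction is None) == (self.multiple_of_pmax is None):
            raise ValueError("give exactly one of counts_fraction or multiple_of_pmax")
        if self.counts_fraction is not None and not (0 < self.counts_fraction < 1):
            raise ValueError("counts_fraction must be in (0, 1)")
        if self.multiple_of_pmax is not None and self.multiple_of_pmax <= 0:
            raise ValueError("multiple_of_pmax must be > 0")


_DEF_LUNGS = (
    Ellipsoid((48.0, 0.0, 0.0), (36.0, 48.0, 84.0)),   # right, slightly larger
    Ellipsoid((-48.0, 0.0, 0.0), (32.0, 46.0, 80.0)),  # left
)
_DEF_BODY = Ellipsoid((0.0, 0.0, 0.0), (100.0, 80.0, 110.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic CT+PET study."""

    grid: ImageGrid = field(default_factory=default_grid)
    body: Ellipsoid = _DEF_BODY
    lungs: Tuple[Ellipsoid, ...] = _DEF_LUNGS
    body_hu: float = 0.0
    exterior_hu: float = -1000.0
    lung_hu: float = -800.0
    activity_pattern: Pattern = Uniform()
    hotspots: Tuple[Hotspot, ...] = ()
    noise_sigma_rel: float = 0.0
    tie_break_rel: float = 1e-6
    seed: int = 0


class FVCurve:
    """Piecewise-linear cumulative activity–volume curve F(v).

    Built from homogeneous segments ``(voxel_count, value)`` sorted by value
    descending; F maps the hottest volume fraction v in [0, 1] to the counts
    fraction it contains. F(0)=0, F(1)=1, non-decreasing and concave.
    """

    def __init__(self, segments: Sequence[Tuple[int, float]]):
        segs = sorted(((int(n), float(a)) for n, a in segments if n > 0),
                      key=lambda s: -s[1])
        if not segs or any(a < 0 for _, a in segs):
            raise ValueError("need nonnegative-valued, nonempty segments")
        n_tot = sum(n for n, _ in segs)
        c_tot = sum(n * a for n, a in segs)
        if c_tot <= 0:
            raise ValueError("total counts must be > 0")
        v = np.concatenate([[0.0], np.cumsum([n for n, _ in segs]) / n_tot])
        F = np.concatenate([[0.0], np.cumsum([n * a for n, a in segs]) / c_tot])
        self.knots_v = v
        self.knots_F = F
        self.segments = segs
        self.total_counts = c_tot
        self.n_voxels = n_tot

    def F(self, v):
        """Counts fraction contained in the hottest volume fraction ``v``."""
        return np.interp(v, self.knots_v, self.knots_F)

    def F_inv(self, counts_fraction):
        """Volume fraction of the minimal region holding ``counts_fraction``."""
        return np.interp(counts_fraction, self.knots_F, self.knots_v)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom (noiseless)."""

    lung_mask: BinaryMask
    total_counts: float
    fv_curve: FVCurve


def _check_inside_grid(e: Ellipsoid, grid: ImageGrid) -> None:
    ext = grid.physical_extent()
    for w in range(3):
        if e.center_mm[w] - e.semi_axes_mm[w] < ext[w, 0] or e.center_mm[w] + e.semi_axes_mm[w] > ext[w, 1]:
            raise LungFVError(f"ellipsoid {e} extends outside the grid on world axis {w}")


def _nearest_k(flat_idx: np.ndarray, coords: Tuple[np.ndarray, ...], point: np.ndarray, k: int) -> np.ndarray:
    d2 = sum((c - p) ** 2 for c, p in zip(coords, point))
    order = np.argsort(d2, kind="stable")
    return order[:k]


def generate_phantom(spec: PhantomSpec) -> Tuple[ScalarVolume, ScalarVolume, PhantomTruth]:
    """Generate ``(ct, pet, truth)`` for a phantom spec; deterministic in seed."""
    grid = spec.grid
    _check_inside_grid(spec.body, grid)
    for e in spec.lungs:
        _check_inside_grid(e, grid)

    cw = grid.voxel_centers_world()
    # world coordinate arrays per voxel axis, broadcast to 3D
    aff = grid.affine
    world_axis_of_voxel_axis = [int(np.nonzero(aff[:3, i])[0][0]) for i in range(3)]
    ax1d = [cw[i] for i in range(3)]
    X = ax1d[0][:, None, None]
    Y = ax1d[1][None, :, None]
    Z = ax1d[2][None, None, :]
    world = [None, None, None]
    for i, w in enumerate(world_axis_of_voxel_axis):
        world[w] = (X, Y, Z)[i]
    xs, ys, zs = world

    body = spec.body.contains(xs, ys, zs)
    lung = np.zeros(grid.shape, dtype=bool)
    for e in spec.lungs:
        lung |= e.contains(xs, ys, zs)
    lung &= body
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise LungFVError("phantom lungs contain no voxels")
    # anatomical validity: a soft-tissue shell must separate lung from
    # exterior air, else HU-based segmentation merges lung with exterior
    shell = ndimage.binary_dilation(lung) & ~lung
    if not body[shell].all():
        raise LungFVError("phantom lungs touch the body surface (no chest-wall shell)")

    ct_vals = np.full(grid.shape, spec.exterior_hu, dtype=np.float64)
    ct_vals[body] = spec.body_hu
    ct_vals[lung] = spec.lung_hu

    rng = np.random.default_rng(spec.seed)
    lung_flat = np.nonzero(lung.ravel())[0]
    lc = tuple(np.broadcast_to(w, grid.shape).ravel()[lung_flat] for w in (xs, ys, zs))

    vals, segments = _pattern_values(spec, lung, lung_flat, lc, grid)

    # hot spots: single voxels, applied sequentially to the noiseless values
    for hs in spec.hotspots:
        vals, segments = _apply_hotspot(hs, vals, segments, lc, rng)

    truth_total = float(vals.sum())
    curve = FVCurve(segments)

    if spec.tie_break_rel > 0:
        vals = vals * (1.0 + spec.tie_break_rel * rng.uniform(-1.0, 1.0, size=vals.shape))
    if spec.noise_sigma_rel > 0:
        vals = np.maximum(vals * (1.0 + spec.noise_sigma_rel * rng.normal(0.0, 1.0, size=vals.shape)), 0.0)

    pet_vals = np.zeros(grid.shape, dtype=np.float64)
    pet_vals.ravel()[lung_flat] = vals

    ct = ScalarVolume(grid, ct_vals, "CT-HU")
    pet = ScalarVolume(grid, pet_vals, "activity")
    truth = PhantomTruth(BinaryMask(grid, lung), truth_total, curve)
    return ct, pet, truth


def _pattern_values(spec, lung, lung_flat, lc, grid):
    """Noiseless per-lung-voxel activity plus closed-form curve segments."""
    n = lung_flat.size
    pat = spec.activity_pattern
    if isinstance(pat, Uniform):
        vals = np.ones(n)
        segments = [(n, 1.0)]
    elif isinstance(pat, LinearGradient):
        coord = lc[_world_axis(grid, pat.axis)]
        cmin, cmax = float(coord.min()), float(coord.max())
        if cmax <= cmin:
            raise LungFVError("gradient axis spans a single slice")
        vals = 1.0 + (pat.ratio - 1.0) * (coord - cmin) / (cmax - cmin)
        uniq, counts = np.unique(vals, return_counts=True)
        segments = list(zip(counts.tolist(), uniq.tolist()))
    elif isinstance(pat, TwoCompartment):
        k = max(1, round(pat.volume_fraction * n))
        hot_idx = _nearest_k(lung_flat, lc, np.array(spec.lungs[0].center_mm), k)
        a_hot = pat.counts_fraction * n / k
        a_cold = (1.0 - pat.counts_fraction) * n / (n - k)
        vals = np.full(n, a_cold)
        vals[hot_idx] = a_hot
        segments = [(k, a_hot), (n - k, a_cold)]
    elif isinstance(pat, Defect):
        k = max(1, round(pat.volume_fraction * n))
        seed_lung = spec.lungs[1] if len(spec.lungs) > 1 else spec.lungs[0]
        cold_idx = _nearest_k(lung_flat, lc, np.array(seed_lung.center_mm), k)
        vals = np.ones(n)
        vals[cold_idx] = pat.scale
        segments = [(n - k, 1.0), (k, pat.scale)]
    else:
        raise LungFVError(f"unknown activity pattern {pat!r}")
    return vals, segments


def _world_axis(grid: ImageGrid, voxel_axis: int) -> int:
    aff = grid.affine
    return int(np.nonzero(aff[:3, voxel_axis])[0][0])


def _apply_hotspot(hs, vals, segments, lc, rng):
    n = vals.size
    if hs.location_mm is not None:
        d2 = sum((c - p) ** 2 for c, p in zip(lc, hs.location_mm))
        i = int(np.argmin(d2))
    else:
        i = int(rng.integers(n))
    old = float(vals[i])
    total = float(vals.sum())
    if hs.counts_fraction is not None:
        new_val = hs.counts_fraction * (total - old) / (1.0 - hs.counts_fraction)
    else:
        new_val = hs.multiple_of_pmax * float(vals.max())
    vals = vals.copy()
    vals[i] = new_val
    # keep the closed-form segment list voxel-exact
    segs = []
    removed = False
    for cnt, a in segments:
        if not removed and abs(a - old) <= 1e-9 * max(abs(a), abs(old), 1e-30):
            removed = True
            cnt -= 1
        if cnt > 0:
            segs.append((cnt, a))
    if not removed:
        raise LungFVError("hotspot bookkeeping failed: source segment not found")
    segs.append((1, new_val))
    return vals, segs


def inject_hotspot(pet: ScalarVolume, av: BinaryMask, counts_fraction: float, seed: int = 0) -> ScalarVolume:
    """Inject a single-voxel hot spot carrying ``counts_fraction`` of the
    *new* total activity at a seeded random AV voxel; returns a new volume."""
    if not (0 < counts_fraction < 1):
        raise LungFVError("counts_fraction must be in (0, 1)")
    if av.voxel_count == 0:
        raise LungFVError("empty AV mask")
    rng = np.random.default_rng(seed)
    flat = np.nonzero(av.values.ravel())[0]
    i = int(flat[rng.integers(flat.size)])
    vals = pet.values.copy().ravel()
    total = float(pet.values[av.values].sum())
    old = float(vals[i])
    vals[i] = counts_fraction * (total - old) / (1.0 - counts_fraction)
    return ScalarVolume(pet.grid, vals.reshape(pet.grid.shape), "activity")


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortStudy:
    """One synthetic patient: imaging, truth, and pulmonary function tests."""

    study_id: str
    spec: PhantomSpec
    ct: ScalarVolume
    pet: ScalarVolume
    truth: PhantomTruth
    fev1_fvc_ratio: Optional[float]
    dlco_pct_predicted: Optional[float]

    @property
    def pft_status(self) -> str:
        return classify_pft(self.fev1_fvc_ratio, self.dlco_pct_predicted)


DEFAULT_PATTERN_MIX = (
    ("uniform", 0.25),
    ("gradient", 0.25),
    ("two_compartment", 0.25),
    ("defect", 0.25),
)


def _random_pattern(kind: str, rng: np.random.Generator) -> Pattern:
    if kind == "uniform":
        return Uniform()
    if kind == "gradient":
        return LinearGradient(axis=int(rng.integers(3)), ratio=float(rng.uniform(2.0, 5.0)))
    if kind == "two_compartment":
        # hot/cold contrast kept moderate so that the cold compartment stays
        # above the 5%-of-pmax scan floor of the iterative method (the scan
        # bracket the method publishes); extreme contrasts trip the boundary
        # flag instead, which is exercised separately
        v = float(rng.uniform(0.30, 0.40))
        f = float(v + rng.uniform(0.15, 0.25))
        return TwoCompartment(v, f)
    if kind == "defect":
        return Defect(float(rng.uniform(0.10, 0.25)), float(rng.uniform(0.10, 0.40)))
    raise LungFVError(f"unknown pattern kind {kind!r}")


def generate_cohort(
    n: int,
    pattern_mix: Sequence[Tuple[str, float]] = DEFAULT_PATTERN_MIX,
    seed: int = 0,
    abnormal_fraction: float = 0.65,
    missing_pft_fraction: float = 0.2,
    noise_sigma_range: Tuple[float, float] = (0.10, 0.18),
    hotspot_prob: float = 0.25,
    grid: Optional[ImageGrid] = None,
) -> List[CohortStudy]:
    """Generate ``n`` reproducible synthetic studies with varied geometry,
    perfusion patterns, and synthetic pulmonary function tests.

    Geometry varies by ±10% per lung semi-axis. A stated fraction of
    patients with PFTs is drawn abnormal (obstruction FEV1/FVC < 0.7 and/or
    diffusion DLCO < 60% predicted); a stated fraction has no PFTs at all.
    Hot spots, when drawn, are moderate (2-4x the bulk maximum).
    """
    if n < 1:
        raise LungFVError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kinds = [k for k, _ in pattern_mix]
    probs = np.array([p for _, p in pattern_mix], dtype=float)
    probs = probs / probs.sum()

    studies = []
    for i in range(n):
        # per-axis scale kept below 1.02 so a chest-wall shell of at least
        # one voxel always separates the lungs from exterior air
        lungs = tuple(
            Ellipsoid(e.center_mm, tuple(a * rng.uniform(0.85, 1.02) for a in e.semi_axes_mm))
            for e in _DEF_LUNGS
        )
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        hotspots: Tuple[Hotspot, ...] = ()
        if rng.random() < hotspot_prob:
            hotspots = (Hotspot(multiple_of_pmax=float(rng.uniform(2.0, 4.0))),)
        spec = PhantomSpec(
            grid=grid or default_grid(),
            lungs=lungs,
            activity_pattern=_random_pattern(kind, rng),
            hotspots=hotspots,
            noise_sigma_rel=float(rng.uniform(*noise_sigma_range)),
            seed=int(rng.integers(2**31)),
        )
        ct, pet, truth = generate_phantom(spec)

        if rng.random() < missing_pft_fraction:
            fev1_fvc: Optional[float] = None
            dlco: Optional[float] = None
        elif rng.random() < abnormal_fraction:
            mode = rng.integers(3)  # obstructive / diffusion / both
            fev1_fvc = float(rng.uniform(0.45, 0.69)) if mode in (0, 2) else float(rng.uniform(0.72, 0.85))
            dlco = float(rng.uniform(30.0, 59.0)) if mode in (1, 2) else float(rng.uniform(65.0, 110.0))
        else:
            fev1_fvc = float(rng.uniform(0.72, 0.85))
            dlco = float(rng.uniform(65.0, 110.0))

        studies.append(
            CohortStudy(f"P{i + 1:03d}", spec, ct, pet, truth, fev1_fvc, dlco)
        )
    return studies
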