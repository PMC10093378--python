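# Methods

## Problem and model

Functional lung avoidance radiotherapy needs a reproducible way to turn a
perfusion image (here: PET of Gallium-68-labelled macroaggregated albumin,
whose voxel values are proportional to regional capillary perfusion) into
contours of "functional lung". `lungfv` implements and compares two
intensity-threshold families inside a CT-derived whole-lung anatomical
volume (AV):

* **pmax method.** Fix `pmax = max` voxel value within the AV and keep AV
  voxels with value *strictly greater than* `X/100 · pmax`. The reference is
  a single pixel, so it inherits that pixel's noise and any artefactual hot
  spot.
* **WLF method** (whole-lung function). Define the relative functional
  value of a region S as

      FV(S) = Σ_{v ∈ S} a(v) / Σ_{v ∈ AV} a(v),

  the fraction of total AV counts inside S. The FV-X% volume is the
  *minimal* volume with FV ≥ X%. Because thresholding keeps the hottest
  voxels first, that minimal volume is always a threshold superlevel set;
  the method's reference is the whole-lung total, which a single voxel
  cannot dominate.

All percentages are voxel-count ratios (volume, as % of the AV) and
value-sum ratios (activity/counts) on one grid, so voxel-volume factors
cancel and no absolute calibration of the activity units is needed —
delineations are invariant under global rescaling of the activity image.

Two realizations of the WLF definition are implemented and continuously
checked against each other:

1. `wlf_delineate_iterative` — the scan formulation: pmax thresholds from
   95% down to 5% in 0.1% steps; for each target the first (largest)
   threshold whose FV reaches the target is selected. The scan is evaluated
   from a single descending sort plus cumulative sums at the 901 scan
   thresholds, mathematically identical to 901 independent segmentations
   (`literal=True` runs them literally; a conformance test asserts
   equality).
2. `wlf_delineate_exact` — the definition itself: sort AV voxels by value
   descending, accumulate whole tie-groups, stop at the shortest
   tie-group-closed prefix reaching the target. No threshold grid is
   involved; this serves as the independent oracle.

The selection rule "largest satisfying threshold" is the unique rule
consistent with minimality at the scan's granularity, since FV is
non-increasing in the threshold.

## Anatomical volume

The AV is contoured on CT by Hounsfield-unit rules: candidate voxels in
(−1024, −300) HU; connected components touching the image boundary removed
(exterior air); the 2 largest remaining components of ≥ 100 ml kept;
morphological closing with a 3 mm ball to reabsorb vessels. These values
are standard lung-CT heuristics; all are parameters (`AVParams`). Manual
review is replaced by logged component statistics and an override: every
operation accepts a user-supplied mask instead. The AV is purely
HU-defined — tumours, effusions and central airways receive no special
treatment; this is a stated limitation, not an oversight. The AV is
segmented on the CT grid and resampled to the PET grid by nearest neighbour
(masks stay binary) before any counting; the 0.01 mm grid-equality
tolerance and NIfTI conventions (float64 volumes, uint8 masks) live in the
I/O layer.

## Numerical conventions

* **Strict inequality** at thresholds ("value > threshold"): the 100%pmax
  volume is empty and the hottest voxel is inside every scanned
  segmentation.
* **Ties.** A threshold cannot split equal-valued voxels, so the exact
  method accumulates whole tie-groups and may overshoot the target; its
  reported threshold is the largest excluded value as % of pmax (0 when
  nothing is excluded), making the mask exactly the strict-threshold
  segmentation at that value.
* **FV comparisons** use an absolute slack of 1e-9 percentage points,
  absorbing float summation error only.
* **Unreachable targets.** If even the 5% scan floor does not reach the
  target (possible when most counts sit in values below 5% of pmax — e.g.
  after an extreme hot spot, or with very high compartment contrast), the
  boundary segmentation is returned with `boundary_flag=True` and a
  warning. The scan is deliberately not extended beyond 5–95%; widen it via
  `WLFParams` if desired.
* **Scan granularity.** Between consecutive scan thresholds FV can jump by
  the counts of all voxels whose values fall within one step
  (0.1% of pmax). On continuous, well-spread value distributions this is a
  fraction of a percentage point; on (near-)constant distributions it is
  the whole tie cluster. Two honest consequences, both asserted in tests:
  on an exactly uniform lung the iterative scan returns the full AV for
  every target (every scanned threshold lies below all values), while the
  exact method returns X% of the AV for target X; and a dominant hot spot
  inflates pmax so far that the scan cannot resolve the bulk at all
  (boundary flag). The exact method is the appropriate realization in both
  regimes.

## Synthetic phantoms

`PhantomSpec` describes a CT (exterior air −1000 HU, soft-tissue body
ellipsoid at 0 HU, two aerated lung ellipsoids at −800 HU) plus an activity
image on a 64³ grid at 4 mm isotropic spacing — the reconstruction scale of
clinical perfusion PET — giving ~17k lung voxels (~1.1 l). Supported
perfusion patterns, each with a closed-form cumulative activity–volume
curve F(v) (counts fraction in the hottest volume fraction v):

| pattern | construction | F |
|---|---|---|
| uniform | constant | F(v) = v |
| linear gradient (`ratio` r) | slice-constant, 1 → r along one axis | piecewise linear from per-slice voxel counts |
| two-compartment (v, f) | the v·N voxels nearest a seed point get value f·N/k, rest (1−f)·N/(N−k) | (0,0)→(v,f)→(1,1) |
| defect (w, s) | a compact sub-region of volume fraction w scaled by s<1 | (0,0)→(1−w, (1−w)/(1−w+ws))→(1,1) |

Compartments are selected by exact voxel count, so the curve knots are
voxel-exact and the exact delineation must recover F⁻¹ within one voxel's
volume share — the recovery tolerance used throughout the tests.

Deliberate departures from raw physical simulation:

* **Tie-breaking jitter** (multiplicative, relative 1e-6, seeded,
  switchable off): reconstructed PET values are continuous, so exact ties
  are measure-zero in practice; the idealized piecewise-constant patterns
  would otherwise form giant tie-groups that no threshold can split.
  1e-6 is far below any modelled contrast and far above float epsilon.
* **Multiplicative Gaussian noise** (σ relative to local value): in
  reconstructed, post-filtered images noise magnitude grows with local
  signal. It also keeps the *relative* spread of every value cluster
  comparable, so the per-step FV jump of the iterative scan stays bounded
  across patterns — with additive noise a hot compartment forms a value
  cluster narrow relative to the 0.1%-of-pmax step, and single-step FV
  jumps exceed a percentage point, which says something about additive
  noise, not about the method. No Poisson counting, scatter, attenuation,
  PSF or respiratory motion is simulated; noise is clamped at zero.
* **Hot spots** are single voxels set either to a stated multiple of the
  current maximum or to carry a stated fraction h of the new total
  (value = h·(T−old)/(1−h), which for h=5% of a ~17k-voxel lung is ~900×
  the bulk mean — the artefactual regime hot spots occupy in practice).

The cohort generator varies lung semi-axes by a factor drawn in
(0.85, 1.02) per axis — the upper bound keeps at least one voxel of
chest-wall shell between lung and exterior air, which the generator also
validates explicitly — draws patterns from a stated mix, noise σ in
(0.10, 0.18), optional moderate hot spots (2–4× pmax, probability 0.25),
and synthetic pulmonary function tests: 20% of patients lack PFTs, 65% of
the rest are abnormal (FEV1/FVC < 0.7 and/or DLCO < 60% predicted), with
values drawn clear of the cutoffs. Perfusion patterns and PFTs are drawn
independently: a significant group difference in a synthetic cohort is a
sampling accident by construction.

The oracle-conformance study conditions (the 200-phantom sweep) use this
mix without hot spots and with the two-compartment contrast constrained to
hot-volume fraction 0.30–0.40 holding counts fraction +0.15..0.25 above its
volume fraction: beyond that, either the cold compartment falls below the
5% scan floor (making FV90 honestly unreachable — the boundary-flag regime,
exercised separately) or its value cluster becomes narrow relative to the
scan step. Hot-spot behaviour has its own dedicated robustness check, where
the pmax method's collapse is the measured outcome, not a nuisance.

## Statistics

* Summaries: median, quartiles by linear interpolation between order
  statistics (`numpy.percentile(..., method="linear")` — the common
  spreadsheet convention, fixed so IQRs are reproducible), min, max, n.
* Group comparison: two-sided two-sample Student's t with pooled variance,
  df = n_a + n_b − 2, sign convention mean(a) − mean(b); Welch's variant
  behind a flag. One-sided tests are not offered.
* PFT classification is strict at the cutoffs (0.7 and 60% are "normal");
  missing or non-positive inputs give status "missing", never silently
  normal, and such patients are excluded from group comparisons.

## Problem sizes and defaults

The default phantom grid (64³ at 4 mm) keeps every delineation under
~50 ms, the 200-phantom conformance sweep under a minute, and the 10-study
end-to-end CLI determinism check a few tens of seconds, while matching the
voxel scale of the clinical images the method targets. The scan defaults
(5–95%, 0.1% steps, targets 10…90%) and the pmax threshold list
(10…60%) are the method's published operating points and are all
configurable.

## Known limitations

* AV segmentation is heuristic HU thresholding: no airway removal, no
  lesion exclusion, no ML; oblique NIfTI affines are rejected rather than
  reoriented.
* Phantoms are geometric idealizations; passing recovery tests demonstrates
  correctness of the delineation arithmetic and its invariances, not
  clinical accuracy on real anatomy, motion, or reconstruction artefacts.
* The iterative scan's fidelity degrades exactly where its reference does
  (near-constant images, dominant hot spots); the package makes this
  visible (boundary flags, exact-method cross-checks) rather than hiding
  it.
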