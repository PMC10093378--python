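import numpy as np
import pytest

import lungfv as lf
from lungfv.core import LungFVError


class TestTruthCurves:
    def test_uniform_curve_is_identity(self):
        _, _, truth = lf.generate_phantom(lf.PhantomSpec(seed=1))
        v = np.linspace(0, 1, 11)
        assert np.allclose(truth.fv_curve.F(v), v)

    def test_two_compartment_breakpoint_exact(self):
        spec = lf.PhantomSpec(activity_pattern=lf.TwoCompartment(0.2, 0.6), seed=2)
        _, _, truth = lf.generate_phantom(spec)
        curve = truth.fv_curve
        n = truth.lung_mask.voxel_count
        k = round(0.2 * n)
        assert curve.F(k / n) == pytest.approx(0.6)
        assert curve.F_inv(0.6) == pytest.approx(k / n)
        # within a voxel of the nominal fractions
        assert curve.F(0.2) == pytest.approx(0.6, abs=3.0 / n * 5)

    @pytest.mark.parametrize(
        "pattern",
        [lf.Uniform(), lf.LinearGradient(ratio=4.0), lf.TwoCompartment(0.25, 0.55), lf.Defect(0.2, 0.3)],
    )
    def test_curve_shape_invariants(self, pattern):
        """F(0)=0, F(1)=1, non-decreasing, concave for all patterns."""
        _, _, truth = lf.generate_phantom(lf.PhantomSpec(activity_pattern=pattern, seed=3))
        v, F = truth.fv_curve.knots_v, truth.fv_curve.knots_F
        assert F[0] == 0.0 and F[-1] == pytest.approx(1.0)
        assert (np.diff(F) >= 0).all()
        slopes = np.diff(F) / np.diff(v)
        assert (np.diff(slopes) <= 1e-9).all()


class TestGeneratePhantom:
    def test_deterministic_bit_identical(self):
        spec = lf.PhantomSpec(activity_pattern=lf.LinearGradient(), noise_sigma_rel=0.1, seed=9)
        ct1, pet1, _ = lf.generate_phantom(spec)
        ct2, pet2, _ = lf.generate_phantom(spec)
        assert np.array_equal(ct1.values, ct2.values)
        assert np.array_equal(pet1.values, pet2.values)

    def test_ct_regions(self):
        spec = lf.PhantomSpec(seed=1)
        ct, pet, truth = lf.generate_phantom(spec)
        lung = truth.lung_mask.values
        assert (ct.values[lung] == spec.lung_hu).all()
        assert ct.values[0, 0, 0] == spec.exterior_hu
        # activity strictly inside lungs
        assert (pet.values[~lung] == 0).all()
        assert (pet.values[lung] > 0).all()

    def test_noise_nonnegative_and_total_within_3_sigma(self):
        spec = lf.PhantomSpec(noise_sigma_rel=0.3, seed=7)
        _, pet, truth = lf.generate_phantom(spec)
        vals = pet.values[truth.lung_mask.values]
        assert (vals >= 0).all()
        # multiplicative noise: sd of the total is sigma * sqrt(sum v^2)
        sigma_total = 0.3 * np.sqrt(truth.lung_mask.voxel_count)  # noiseless values are 1
        assert abs(vals.sum() - truth.total_counts) <= 3.5 * sigma_total

    def test_geometry_outside_grid_rejected(self):
        bad = lf.PhantomSpec(lungs=(lf.Ellipsoid((0, 0, 0), (300.0, 50.0, 50.0)),))
        with pytest.raises(LungFVError, match="outside the grid"):
            lf.generate_phantom(bad)

    def test_spec_hotspot_multiple_of_pmax(self):
        spec = lf.PhantomSpec(
            activity_pattern=lf.LinearGradient(ratio=3.0),
            hotspots=(lf.Hotspot(multiple_of_pmax=2.0),),
            tie_break_rel=0.0,
            seed=12,
        )
        _, pet, truth = lf.generate_phantom(spec)
        vals = pet.values[truth.lung_mask.values]
        top, second = np.sort(vals)[-2:][::-1]
        assert top == pytest.approx(2.0 * 3.0, rel=1e-6)
        # truth curve accounts for the injected voxel
        assert truth.fv_curve.segments[0] == (1, pytest.approx(6.0))


class TestInjectHotspot:
    def test_half_counts_identity(self, default_phantom):
        _, pet, truth = default_phantom
        av = truth.lung_mask
        after = lf.inject_hotspot(pet, av, 0.5, seed=3)
        hot = lf.BinaryMask(av.grid, after.values == after.values.max())
        assert hot.voxel_count == 1
        assert lf.fv_of_mask(after, av, hot) == pytest.approx(50.0)

    def test_small_fraction_dwarfs_pmax(self, gradient_phantom):
        _, pet, truth = gradient_phantom
        av = truth.lung_mask
        before = lf.pmax_value(pet, av)
        after = lf.inject_hotspot(pet, av, 0.05, seed=3)
        assert lf.pmax_value(after, av) >= 10 * before

    def test_two_sequential_injections(self, default_phantom):
        _, pet, truth = default_phantom
        av = truth.lung_mask
        once = lf.inject_hotspot(pet, av, 0.1, seed=1)
        twice = lf.inject_hotspot(once, av, 0.1, seed=2)
        vals = np.sort(twice.values[av.values])
        assert vals[-2:].sum() / vals.sum() >= 0.19

    def test_bad_fraction_rejected(self, default_phantom):
        _, pet, truth = default_phantom
        with pytest.raises(LungFVError):
            lf.inject_hotspot(pet, truth.lung_mask, 1.5, seed=0)


class TestCohort:
    def test_reproducible_bit_for_bit(self):
        a = lf.generate_cohort(3, seed=77)
        b = lf.generate_cohort(3, seed=77)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.pet.values, sb.pet.values)
            assert sa.fev1_fvc_ratio == sb.fev1_fvc_ratio
            assert sa.dlco_pct_predicted == sb.dlco_pct_predicted

    def test_abnormal_fraction_binomial(self):
        studies = lf.generate_cohort(60, seed=5, abnormal_fraction=0.65)
        statuses = [s.pft_status for s in studies]
        with_pft = [s for s in statuses if s != "missing"]
        n_ab = sum(s == "abnormal" for s in with_pft)
        n = len(with_pft)
        # binomial 3-sigma band around 65%
        sd = np.sqrt(n * 0.65 * 0.35)
        assert abs(n_ab - 0.65 * n) <= 3 * sd
        # some patients skip PFTs entirely
        assert statuses.count("missing") > 0

    def test_status_consistent_with_classifier(self):
        for s in lf.generate_cohort(8, seed=2):
            assert s.pft_status == lf.classify_pft(s.fev1_fvc_ratio, s.dlco_pct_predicted)
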