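import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lungfv as lf
from lungfv.core import LungFVError
from conftest import make_study


class TestPmaxValue:
    def test_four_voxel(self, four_voxel):
        assert lf.pmax_value(*four_voxel) == 10.0

    def test_uniform(self):
        assert lf.pmax_value(*make_study([7.0] * 5)) == 7.0

    def test_hotspot_phantom(self):
        spec = lf.PhantomSpec(
            activity_pattern=lf.Uniform(),
            hotspots=(lf.Hotspot(multiple_of_pmax=500.0),),
            tie_break_rel=0.0,
            seed=4,
        )
        _, pet, truth = lf.generate_phantom(spec)
        assert lf.pmax_value(pet, truth.lung_mask) == pytest.approx(500.0)

    def test_errors(self, four_voxel):
        pet, av = four_voxel
        empty = lf.BinaryMask(av.grid, np.zeros(av.grid.shape, bool))
        with pytest.raises(LungFVError, match="empty AV"):
            lf.pmax_value(pet, empty)
        zero_pet, av2 = make_study([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(LungFVError, match="no activity"):
            lf.pmax_value(zero_pet, av2)


class TestThresholdSegment:
    @pytest.mark.parametrize(
        "pct,vol,act",
        [(50.0, 25.0, 50.0), (40.0, 50.0, 75.0), (100.0, 0.0, 0.0)],
    )
    def test_hand_enumeration(self, four_voxel, pct, vol, act):
        seg = lf.threshold_segment(*four_voxel, pct)
        assert seg.volume_pct_av == pytest.approx(vol)
        assert seg.activity_pct_total == pytest.approx(act)

    def test_strict_inequality_keeps_hottest_voxel_below_100(self, four_voxel):
        # any sub-maximal threshold includes the hottest voxel
        assert lf.threshold_segment(*four_voxel, 99.0).mask.voxel_count == 1
        # at 100% the strict inequality empties the mask
        assert lf.threshold_segment(*four_voxel, 100.0).mask.voxel_count == 0


class TestFvOfMask:
    def test_identity_empty_and_half(self, four_voxel):
        pet, av = four_voxel
        assert lf.fv_of_mask(pet, av, av) == pytest.approx(100.0)
        empty = lf.BinaryMask(av.grid, np.zeros(av.grid.shape, bool))
        assert lf.fv_of_mask(pet, av, empty) == 0.0
        two = lf.BinaryMask(av.grid, pet.values >= 5.0)
        assert lf.fv_of_mask(pet, av, two) == pytest.approx(75.0)

    def test_non_subset_rejected(self, four_voxel):
        pet, av = four_voxel
        sub = lf.BinaryMask(av.grid, pet.values >= 5.0)
        with pytest.raises(LungFVError, match="not contained"):
            lf.fv_of_mask(pet, sub, av)


class TestPmaxSeries:
    def test_order_and_nesting(self, four_voxel):
        segs = lf.pmax_series(*four_voxel, [40.0, 50.0])
        assert [s.volume_pct_av for s in segs] == [50.0, 25.0]
        assert segs[1].mask.is_subset_of(segs[0].mask)

    def test_uniform_selects_everything(self):
        segs = lf.pmax_series(*make_study([3.0] * 6), [10, 60, 99])
        for s in segs:
            assert s.volume_pct_av == 100.0
            assert s.activity_pct_total == 100.0

    def test_volume_monotone_against_sorted_oracle(self, gradient_phantom):
        _, pet, truth = gradient_phantom
        av = truth.lung_mask
        segs = lf.pmax_series(pet, av, lf.DEFAULT_PMAX_PCTS)
        vols = [s.volume_pct_av for s in segs]
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        # sorted-value oracle for the counts above each threshold
        vals = np.sort(pet.values[av.values])[::-1]
        pmax = vals[0]
        for s in segs:
            k = int((vals > pmax * s.threshold_pct_pmax / 100).sum())
            assert s.mask.voxel_count == k


class TestWlfIterative:
    def test_four_voxel_target_50(self, four_voxel):
        res = lf.wlf_delineate_iterative(*four_voxel, lf.WLFParams(targets=(50.0,)))[0]
        # the first scanned threshold (95%) already keeps only voxel 10,
        # which alone holds 50% of counts
        assert res.threshold_pct_pmax == pytest.approx(95.0)
        assert res.achieved_fv_pct == pytest.approx(50.0)
        assert res.volume_pct_av == pytest.approx(25.0)
        assert not res.boundary_flag

    def test_literal_and_fast_paths_agree(self, gradient_phantom):
        _, pet, truth = gradient_phantom
        av = truth.lung_mask
        params = lf.WLFParams(targets=(30.0, 70.0))
        fast = lf.wlf_delineate_iterative(pet, av, params)
        literal = lf.wlf_delineate_iterative(pet, av, params, literal=True)
        for a, b in zip(fast, literal):
            assert a.threshold_pct_pmax == b.threshold_pct_pmax
            assert a.mask.same_voxels(b.mask)
            assert a.achieved_fv_pct == b.achieved_fv_pct

    def test_unreachable_target_sets_boundary_flag(self):
        # one dominant voxel: at the 5% scan floor only it is selected,
        # holding ~83% of counts, so FV90 cannot be bracketed
        pet, av = make_study([500.0] + [1.0] * 100)
        res = lf.wlf_delineate_iterative(pet, av, lf.WLFParams(targets=(90.0,)))[0]
        assert res.boundary_flag
        assert res.threshold_pct_pmax == pytest.approx(5.0)
        assert res.achieved_fv_pct < 90.0
        assert res.mask.voxel_count == 1

    def test_masks_nested_across_targets(self, gradient_phantom):
        _, pet, truth = gradient_phantom
        res = lf.wlf_delineate_iterative(pet, truth.lung_mask)
        for a, b in zip(res, res[1:]):
            assert a.mask.is_subset_of(b.mask)


class TestWlfExact:
    @pytest.mark.parametrize(
        "target,fv,vol,thr",
        [(50.0, 50.0, 25.0, 50.0), (80.0, 90.0, 75.0, 20.0)],
    )
    def test_four_voxel(self, four_voxel, target, fv, vol, thr):
        res = lf.wlf_delineate_exact(*four_voxel, [target])[0]
        assert res.achieved_fv_pct == pytest.approx(fv)
        assert res.volume_pct_av == pytest.approx(vol)
        assert res.threshold_pct_pmax == pytest.approx(thr)

    def test_tie_group_is_indivisible(self):
        res = lf.wlf_delineate_exact(*make_study([5.0] * 4), [30.0])[0]
        assert res.volume_pct_av == 100.0
        assert res.achieved_fv_pct == 100.0
        assert res.threshold_pct_pmax == 0.0

    def test_matches_iterative_on_continuous_phantom(self, gradient_phantom):
        _, pet, truth = gradient_phantom
        av = truth.lung_mask
        it = lf.wlf_delineate_iterative(pet, av)
        ex = lf.wlf_delineate_exact(pet, av)
        for a, b in zip(it, ex):
            assert abs(a.achieved_fv_pct - b.achieved_fv_pct) <= 1.0


@given(
    values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=40),
    target=st.floats(5.0, 95.0),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_exact_oracle_minimality_property(values, target):
    """The exact mask reaches the target, and shedding its boundary
    tie-group drops below the target (minimal tie-closed prefix)."""
    pet, av = make_study(values)
    res = lf.wlf_delineate_exact(pet, av, [target])[0]
    assert res.achieved_fv_pct >= target - 1e-9
    included = pet.values[res.mask.values]
    inner = lf.BinaryMask(av.grid, pet.values > included.min())
    assert lf.fv_of_mask(pet, av, inner) < target + 1e-9
    # enrichment: counts fraction never below volume fraction
    assert res.achieved_fv_pct >= res.volume_pct_av - 1e-9


@given(
    values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=40),
    t1=st.floats(1.0, 100.0),
    t2=st.floats(1.0, 100.0),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_threshold_nesting_and_enrichment_property(values, t1, t2):
    pet, av = make_study(values)
    hi, lo = max(t1, t2), min(t1, t2)
    s_hi = lf.threshold_segment(pet, av, hi)
    s_lo = lf.threshold_segment(pet, av, lo)
    assert s_hi.mask.is_subset_of(s_lo.mask)
    for s in (s_hi, s_lo):
        assert s.activity_pct_total >= s.volume_pct_av - 1e-9


def test_complement_mask(four_voxel):
    pet, av = four_voxel
    fv = lf.wlf_delineate_exact(pet, av, [80.0])[0]
    comp = lf.complement_mask(av, fv.mask)
    assert comp.voxel_count + fv.mask.voxel_count == av.voxel_count
    assert not np.logical_and(comp.values, fv.mask.values).any()


def test_preset_targets_exposed():
    assert lf.PRESET_TARGETS["highly_functional"] == 50.0
    assert lf.PRESET_TARGETS["intermediate"] == 70.0
    assert lf.PRESET_TARGETS["poorly_functional_complement"] == 90.0
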