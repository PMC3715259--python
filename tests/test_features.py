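import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geomexpr import (
    FeatureDescriptor,
    LandmarkSequence,
    build_feature_pool,
    extract_all,
    region_summary,
    type1_feature,
    type2_feature,
)
from geomexpr.features import wrap_angle

from conftest import random_sequence


def seq_from(coords):
    return LandmarkSequence(coords=np.asarray(coords, dtype=float))


class TestDescriptor:
    def test_validation(self):
        FeatureDescriptor("type1", 3)
        FeatureDescriptor("type2", 1, 4)
        with pytest.raises(ValueError):
            FeatureDescriptor("type2", 4, 1)
        with pytest.raises(ValueError):
            FeatureDescriptor("type2", 2, 2)
        with pytest.raises(ValueError):
            FeatureDescriptor("type3", 0)
        with pytest.raises(ValueError):
            FeatureDescriptor("type1", 0, 5)


class TestPool:
    @pytest.mark.parametrize("L,total,type2", [(52, 1378, 1326), (2, 3, 1), (5, 15, 10)])
    def test_pool_sizes(self, L, total, type2):
        pool = build_feature_pool(L)
        assert len(pool) == total
        assert sum(f.kind == "type2" for f in pool) == type2

    def test_pool_formula_range(self):
        for L in range(2, 61):
            assert len(build_feature_pool(L)) == L + L * (L - 1) // 2

    def test_ordering(self):
        pool = build_feature_pool(3)
        assert [repr(f) for f in pool] == [
            "type1(0)", "type1(1)", "type1(2)",
            "type2(0,1)", "type2(0,2)", "type2(1,2)",
        ]

    def test_too_small(self):
        with pytest.raises(ValueError):
            build_feature_pool(1)


class TestType1:
    def test_static_landmark_zero(self):
        s = seq_from([[(3, 3)] * 4, [(1, 2)] * 4])
        np.testing.assert_array_equal(type1_feature(s, 0), np.zeros((3, 2)))

    def test_hand_example(self):
        s = seq_from([[(0, 0), (1, 2), (3, 4)], [(0, 0)] * 3])
        np.testing.assert_allclose(type1_feature(s, 0), [(1, 2), (3, 4)])

    def test_matches_loop_oracle(self, rng):
        s = random_sequence(rng, L=4, F=7)
        for i in range(4):
            expect = [s.coords[i, l] - s.coords[i, 0] for l in range(1, 7)]
            np.testing.assert_allclose(type1_feature(s, i), expect, atol=1e-12)

    def test_out_of_range(self, rng):
        with pytest.raises(IndexError):
            type1_feature(random_sequence(rng, L=3), 3)


class TestType2:
    def test_static_pair_zero(self):
        s = seq_from([[(0, 0)] * 5, [(3, 4)] * 5])
        np.testing.assert_array_equal(type2_feature(s, 0, 1), np.zeros((4, 2)))

    def test_quarter_turn(self):
        # i fixed at origin; j moves from (1,0) to (0,1): d stays 1, angle +pi/2
        s = seq_from([[(0, 0), (0, 0)], [(1, 0), (0, 1)]])
        np.testing.assert_allclose(type2_feature(s, 0, 1), [(0.0, np.pi / 2)], atol=1e-12)

    def test_wrap_convention(self):
        # angle from 175 deg to -175 deg is a +10 deg change after wrapping
        a0 = np.deg2rad(175.0)
        a1 = np.deg2rad(-175.0)
        s = seq_from(
            [[(0, 0), (0, 0)], [(np.cos(a0), np.sin(a0)), (np.cos(a1), np.sin(a1))]]
        )
        dtheta = type2_feature(s, 0, 1)[0, 1]
        np.testing.assert_allclose(np.rad2deg(dtheta), 10.0, atol=1e-9)

    def test_swap_invariance(self, rng):
        # the i<j convention: swapping endpoints flips theta by pi, which
        # cancels in the wrapped difference
        s = random_sequence(rng, L=3, F=6)
        v = type2_feature(s, 0, 2)
        swapped = s.with_coords(s.coords[[2, 1, 0]])
        np.testing.assert_allclose(type2_feature(swapped, 0, 2), v, atol=1e-9)

    def test_coincident_frame0_rejected(self):
        s = seq_from([[(1, 1), (0, 0)], [(1, 1), (2, 2)]])
        with pytest.raises(ValueError, match="coincide"):
            type2_feature(s, 0, 1)

    def test_coincident_later_carries_angle(self):
        s = seq_from([[(0, 0), (1, 0), (0, 0)], [(1, 0), (1, 0), (0, 0)]])
        with pytest.warns(RuntimeWarning):
            v = type2_feature(s, 0, 1)
        # frame 2: pair coincides; angle carried from frame 1
        assert np.isfinite(v).all()


class TestExtractAll:
    def test_cardinality_and_consistency(self, rng):
        s = random_sequence(rng, L=5, F=8)
        pool = build_feature_pool(5)
        fs = extract_all(s, pool)
        assert len(fs) == 15 and fs.values.shape == (15, 7, 2)
        for f in pool:
            if f.kind == "type1":
                np.testing.assert_allclose(fs[f], type1_feature(s, f.i), atol=1e-12)
            else:
                np.testing.assert_allclose(fs[f], type2_feature(s, f.i, f.j), atol=1e-12)

    def test_static_sequence_all_zero(self):
        coords = np.tile(np.array([[(0.0, 0), (5, 0), (0, 7)]]).reshape(3, 1, 2), (1, 6, 1))
        fs = extract_all(LandmarkSequence(coords=coords), build_feature_pool(3))
        np.testing.assert_allclose(fs.values, 0.0, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = random_sequence(rng, L=4, F=6)
        shift = rng.normal(0, 50, size=2)
        moved = s.with_coords(s.coords + shift)
        pool = build_feature_pool(4)
        np.testing.assert_allclose(
            extract_all(moved, pool).values, extract_all(s, pool).values, atol=1e-9
        )

    def test_rotation_invariance_of_type2(self, rng):
        # rotating every frame identically cancels in both d and theta differences
        s = random_sequence(rng, L=4, F=6)
        ang = 0.73
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rot = s.with_coords(s.coords @ R.T)
        pool = [f for f in build_feature_pool(4) if f.kind == "type2"]
        a = extract_all(s, pool).values
        b = extract_all(rot, pool).values
        np.testing.assert_allclose(b, a, atol=1e-9)


class TestRegionSummary:
    def test_pair_across_regions(self):
        sel = [FeatureDescriptor("type2", 0, 1)]
        counts = region_summary(sel, {0: "R1", 1: "R2"})
        assert counts == {("R1", "R2"): 1}

    def test_within_region(self):
        sel = [FeatureDescriptor("type1", 0), FeatureDescriptor("type2", 0, 1)]
        counts = region_summary(sel, {0: "R3", 1: "R3"})
        assert counts == {("R3",): 2}

    def test_conservation(self, rng):
        pool = build_feature_pool(6)
        sel = [pool[k] for k in rng.choice(len(pool), size=10, replace=False)]
        regions = {i: f"R{i % 3}" for i in range(6)}
        counts = region_summary(sel, regions)
        assert sum(counts.values()) == len(sel)

    def test_unmapped_landmark(self):
        with pytest.raises(KeyError):
            region_summary([FeatureDescriptor("type1", 5)], {0: "R1"})


def test_wrap_angle_interval():
    x = np.linspace(-10, 10, 2001)
    w = wrap_angle(x)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    np.testing.assert_allclose(np.cos(w), np.cos(x), atol=1e-12)
    np.testing.assert_allclose(np.sin(w), np.sin(x), atol=1e-12)
    assert wrap_angle(np.pi) == np.pi and wrap_angle(-np.pi) == np.pi
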