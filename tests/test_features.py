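"""Feature computations: worked examples, oracle equivalence, invariances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import mirror_sequence, random_sequence
from emokin import features as F
from emokin.pose import CANONICAL_KEYPOINTS, PoseSequence
from oracles import FEATURE_ORACLES


def _seq_from(frames):
    return PoseSequence("s", "neutral", "a", np.asarray(frames, float))


def _standing(n_frames=5):
    """A fixed plausible standing pose repeated over frames."""
    base = {
        "nose": (0, -45), "neck": (0, 0),
        "r_shoulder": (-33, 0), "r_elbow": (-40, 48), "r_wrist": (-42, 95),
        "l_shoulder": (33, 0), "l_elbow": (40, 48), "l_wrist": (42, 95),
        "r_hip": (-21, 90), "r_knee": (-23, 160), "r_ankle": (-24, 230),
        "l_hip": (21, 90), "l_knee": (23, 160), "l_ankle": (24, 230),
    }
    frame = np.array([base[k] for k in CANONICAL_KEYPOINTS], float)
    return _seq_from(np.tile(frame, (n_frames, 1, 1)))


class TestWorkedExamples:
    def test_velocity_345_triangle(self):
        frames = np.zeros((2, 14, 2))
        frames[1, 0] = (3.0, 4.0)
        v = F.compute_velocity(_seq_from(frames))
        assert v.values.shape == (1, 14)
        assert v.values[0, 0] == 5.0
        assert np.all(v.values[0, 1:] == 0.0)

    def test_static_skeleton_zero_kinematics(self):
        seq = _standing()
        assert np.all(F.compute_velocity(seq).values == 0)
        assert np.all(F.compute_acceleration(seq).values == 0)
        assert np.all(F.compute_vertical_movement(seq).values == 0)

    def test_uniform_motion_zero_acceleration(self):
        seq = _standing(6)
        drift = np.arange(6)[:, None, None] * np.array([2.0, -1.0])
        seq = _seq_from(seq.frames + drift)
        assert np.allclose(F.compute_acceleration(seq).values, 0.0, atol=1e-12)
        assert np.allclose(F.compute_velocity(seq).values, np.sqrt(5.0))

    def test_vertical_movement_sign_up_positive(self):
        frames = np.tile(_standing(2).frames, (1, 1, 1))
        frames[1, :, 1] -= 3.0  # image y decreases: upward motion
        vm = F.compute_vertical_movement(_seq_from(frames))
        assert np.allclose(vm.values, 3.0)

    def test_elbow_angle_straight_and_right(self):
        seq = _standing(1)
        frames = seq.frames.copy()
        kp = {n: CANONICAL_KEYPOINTS.index(n) for n in CANONICAL_KEYPOINTS}
        frames[0, kp["l_shoulder"]] = (10.0, 5.0)
        frames[0, kp["l_elbow"]] = (11.0, 5.0)
        frames[0, kp["l_wrist"]] = (12.0, 5.0)
        straight = F.compute_limb_angles(_seq_from(frames))
        i = straight.component_names.index("l_elbow")
        assert straight.values[0, i] == pytest.approx(180.0)
        frames[0, kp["l_wrist"]] = (11.0, 6.0)
        right = F.compute_limb_angles(_seq_from(frames))
        assert right.values[0, i] == pytest.approx(90.0)

    def test_coincident_joints_undefined_angle(self):
        seq = _standing(1)
        frames = seq.frames.copy()
        i = CANONICAL_KEYPOINTS.index("l_elbow")
        frames[0, CANONICAL_KEYPOINTS.index("l_wrist")] = frames[0, i]
        with pytest.raises(F.UndefinedAngleError, match="l_elbow"):
            F.compute_limb_angles(_seq_from(frames))

    def test_symmetry_mirror_pose_and_offset(self):
        seq = _standing(1)
        frames = seq.frames.copy()
        kp = {n: CANONICAL_KEYPOINTS.index(n) for n in CANONICAL_KEYPOINTS}
        frames[0, kp["nose"], 0] = 0.0
        frames[0, kp["l_wrist"], 0] = 5.0
        frames[0, kp["r_wrist"], 0] = -5.0
        sym = F.compute_symmetry(_seq_from(frames))
        i = sym.component_names.index("wrist")
        assert sym.values[0, i] == 0.0
        frames[0, kp["l_wrist"], 0] = 2.0
        frames[0, kp["r_wrist"], 0] = -6.0
        sym = F.compute_symmetry(_seq_from(frames))
        assert sym.values[0, i] == pytest.approx(4.0)

    def test_shoulder_ratio_extent_cases(self):
        seq = _standing(1)
        frames = seq.frames.copy()
        kp = {n: CANONICAL_KEYPOINTS.index(n) for n in CANONICAL_KEYPOINTS}
        # squeeze all x inside the shoulder span -> ratio 1
        xs = frames[0, :, 0]
        lo, hi = frames[0, kp["r_shoulder"], 0], frames[0, kp["l_shoulder"], 0]
        frames[0, :, 0] = np.clip(xs, lo, hi)
        frames[0, kp["r_shoulder"], 1] = frames[0, kp["l_shoulder"], 1]
        r = F.compute_shoulder_ratio(_seq_from(frames))
        assert r.values[0, 0] == pytest.approx(1.0)
        # stretch wrists so the extent doubles the span -> ratio 0.5
        span = hi - lo
        frames[0, kp["l_wrist"], 0] = lo + 1.5 * span
        frames[0, kp["r_wrist"], 0] = lo - 0.5 * span
        r = F.compute_shoulder_ratio(_seq_from(frames))
        assert r.values[0, 0] == pytest.approx(0.5)

    def test_surface_bounding_box(self):
        frames = np.zeros((1, 14, 2))
        frames[0, 0] = (10.0, 20.0)
        assert F.compute_surface(_seq_from(frames)).values[0, 0] == 200.0

    def test_limb_contraction_mean(self):
        seq = _standing(1)
        frames = seq.frames.copy()
        kp = {n: CANONICAL_KEYPOINTS.index(n) for n in CANONICAL_KEYPOINTS}
        frames[0, kp["nose"]] = (0.0, 0.0)
        frames[0, kp["l_wrist"]] = (50.0, 0.0)
        frames[0, kp["r_wrist"]] = (0.0, 50.0)
        frames[0, kp["l_ankle"]] = (150.0, 0.0)
        frames[0, kp["r_ankle"]] = (0.0, 150.0)
        lc = F.compute_limb_contraction(_seq_from(frames))
        assert lc.values[0, 0] == pytest.approx(100.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("feature", F.FEATURE_NAMES)
    def test_matches_brute_force(self, feature):
        rng = np.random.default_rng(123)
        for _ in range(200):
            seq = random_sequence(rng, n_frames=int(rng.integers(3, 12)))
            got = F.compute_feature(seq, feature).values
            want = FEATURE_ORACLES[feature](seq.frames)
            np.testing.assert_allclose(got, want, atol=1e-9)


class TestInvariances:
    @pytest.fixture()
    def seq(self):
        return random_sequence(np.random.default_rng(11), n_frames=10)

    def test_postural_translation_invariance(self, seq):
        shifted = PoseSequence("s", "neutral", "a", seq.frames + [123.0, -77.0])
        for name in F.POSTURAL_FEATURES:
            np.testing.assert_allclose(
                F.compute_feature(shifted, name).values,
                F.compute_feature(seq, name).values, atol=1e-8,
            )

    def test_angles_rotation_scale_invariance(self, seq):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        transformed = PoseSequence(
            "s", "neutral", "a", 3.0 * seq.frames @ R.T + [5.0, 9.0]
        )
        np.testing.assert_allclose(
            F.compute_limb_angles(transformed).values,
            F.compute_limb_angles(seq).values, atol=1e-8,
        )

    def test_kinematic_and_symmetry_linear_scaling(self, seq):
        scaled = PoseSequence("s", "neutral", "a", 2.0 * seq.frames)
        for name in ("velocity", "acceleration", "vertical_movement",
                     "symmetry"):
            np.testing.assert_allclose(
                F.compute_feature(scaled, name).values,
                2.0 * F.compute_feature(seq, name).values, atol=1e-8,
            )
        np.testing.assert_allclose(
            F.compute_surface(scaled).values,
            4.0 * F.compute_surface(seq).values, atol=1e-6,
        )

    def test_mirror_behaviour(self, seq):
        mirrored = mirror_sequence(seq)
        for name in ("symmetry", "shoulder_ratio", "surface",
                     "limb_contraction"):
            np.testing.assert_allclose(
                F.compute_feature(mirrored, name).values,
                F.compute_feature(seq, name).values, atol=1e-8,
            )
        a = F.compute_limb_angles(seq)
        b = F.compute_limb_angles(mirrored)
        for i, site in enumerate(a.component_names):
            swapped = ("l_" + site[2:]) if site.startswith("r_") else (
                "r_" + site[2:]
            )
            j = a.component_names.index(swapped)
            np.testing.assert_allclose(b.values[:, j], a.values[:, i],
                                       atol=1e-8)


class TestAggregation:
    def test_constant_series_any_aggregation(self):
        s = F.FeatureSeries("velocity", np.full((5, 3), 2.5),
                            ("a", "b", "c"), "px/frame")
        assert F.aggregate(s, over_time=True, over_components=True) == 2.5

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        arrays(np.float64, (6, 3),
               elements=st.floats(-1e6, 1e6, allow_nan=False)),
    )
    def test_means_commute_property(self, values):
        s = F.FeatureSeries("velocity", values, ("a", "b", "c"), "px/frame")
        tc = F.aggregate(F.aggregate(s, over_time=True), over_components=True)
        ct = F.aggregate(F.aggregate(s, over_components=True), over_time=True)
        assert tc == pytest.approx(ct, abs=1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.floats(-1e4, 1e4, allow_nan=False),
        st.floats(-1e4, 1e4, allow_nan=False),
    )
    def test_postural_translation_invariance_property(self, dx, dy):
        seq = random_sequence(np.random.default_rng(0), n_frames=6)
        shifted = PoseSequence("s", "neutral", "a", seq.frames + [dx, dy])
        for name in F.POSTURAL_FEATURES:
            np.testing.assert_allclose(
                F.compute_feature(shifted, name).values,
                F.compute_feature(seq, name).values, atol=1e-6,
            )

    def test_means_commute(self):
        rng = np.random.default_rng(2)
        s = F.FeatureSeries("velocity", rng.normal(size=(7, 4)),
                            ("a", "b", "c", "d"), "px/frame")
        tc = F.aggregate(F.aggregate(s, over_time=True), over_components=True)
        ct = F.aggregate(F.aggregate(s, over_components=True), over_time=True)
        assert tc == pytest.approx(ct, abs=1e-12)

    def test_double_aggregation_noop(self):
        s = F.FeatureSeries("surface", np.arange(6.0)[:, None], ("surface",),
                            "px^2")
        once = F.aggregate(s, over_time=True)
        again = F.aggregate(once, over_time=True)
        np.testing.assert_array_equal(again.values, once.values)


class TestFeatureTable:
    def test_averaged_shape_and_consistency(self, small_stimulus_set):
        table = F.build_feature_table(small_stimulus_set, "averaged")
        assert table.data.shape == (16, 8)
        seq = small_stimulus_set.sequences[3]
        row = table.data.loc[seq.stimulus_id]
        for name in F.FEATURE_NAMES:
            expected = F.aggregate(
                F.compute_feature(seq, name), over_time=True,
                over_components=True,
            )
            assert row[name] == pytest.approx(expected, rel=1e-12)

    def test_time_preserving_column_count(self, small_stimulus_set):
        table = F.build_feature_table(small_stimulus_set, "time_preserving")
        # truncated to the acceleration axis: 8 x (25 - 2) columns
        assert table.data.shape == (16, 8 * 23)

    def test_csv_roundtrip(self, small_stimulus_set, tmp_path):
        table = F.build_feature_table(small_stimulus_set, "averaged")
        table.to_csv(tmp_path / "feat.csv")
        back = F.FeatureTable.from_csv(tmp_path / "feat.csv")
        assert back.mode == "averaged"
        np.testing.assert_array_equal(back.data.to_numpy(),
                                      table.data.to_numpy())
        assert list(back.emotions) == list(table.emotions)
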