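"""Synthetic generators: determinism, exact means, design counts, orderings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emokin import stats
from emokin.features import FEATURE_NAMES, build_feature_table
from emokin.pose import EMOTIONS
from emokin.synthetic import (
    EmotionProfile,
    GeneratorConfig,
    RatingGeneratorConfig,
    default_confusion,
    generate_feature_table,
    generate_ratings,
    generate_stimulus_set,
    generate_time_coded_tables,
)


def _zero_sd(profiles):
    return {
        e: EmotionProfile(p.emotion, p.feature_means,
                          {f: 0.0 for f in p.feature_sds}, p.motion_params)
        for e, p in profiles.items()
    }


def _identity_confusion():
    return {
        e: {f: (1.0 if e == f else 0.0) for f in EMOTIONS} for e in EMOTIONS
    }


class TestProfiles:
    def test_reference_means(self, profiles):
        # spot values from the study's per-emotion feature means
        assert profiles["fear"].feature_means["limb_angles"] == 121.27
        assert profiles["neutral"].feature_means["shoulder_ratio"] == 0.69
        assert profiles["anger"].feature_means["vertical_movement"] == 0.39
        assert profiles["neutral"].feature_means["velocity"] == 1.9
        assert profiles["fear"].feature_means["limb_contraction"] == 684.63

    def test_negative_sd_rejected(self, profiles):
        p = profiles["anger"]
        with pytest.raises(ValueError, match="negative"):
            EmotionProfile(p.emotion, p.feature_means,
                           {f: -1.0 for f in p.feature_sds}, p.motion_params)


class TestFeatureLevelGenerator:
    def test_design_counts(self, profiles):
        table = generate_feature_table(profiles, GeneratorConfig(seed=0))
        assert table.data.shape == (56, 8)
        assert table.emotions.value_counts().to_dict() == {
            e: 14 for e in EMOTIONS
        }

    def test_zero_sd_exact_means(self, profiles):
        table = generate_feature_table(_zero_sd(profiles),
                                       GeneratorConfig(seed=1))
        for emo in EMOTIONS:
            rows = table.data[table.emotions == emo]
            for f in FEATURE_NAMES:
                assert np.allclose(
                    rows[f], profiles[emo].feature_means[f], atol=1e-12
                )

    def test_seed_determinism(self, profiles):
        a = generate_feature_table(profiles, GeneratorConfig(seed=5))
        b = generate_feature_table(profiles, GeneratorConfig(seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)


class TestSkeletonGenerator:
    def test_shapes(self, default_stimulus_set):
        assert len(default_stimulus_set) == 56
        for seq in default_stimulus_set:
            assert seq.frames.shape == (25, 14, 2)

    def test_static_config_zero_velocity(self, profiles):
        from emokin.synthetic import MotionParams
        static = {
            e: EmotionProfile(
                p.emotion, p.feature_means, p.feature_sds,
                MotionParams(p.motion_params.limb_flexion_mean, 0.0,
                             p.motion_params.swing_frequency, 0.0, 0.0, 0.0),
            )
            for e, p in profiles.items()
        }
        cfg = GeneratorConfig(n_per_category=2, n_actors=1, jitter_sd=0.0,
                              seed=0)
        table = build_feature_table(generate_stimulus_set(static, cfg))
        assert np.allclose(table.data["velocity"], 0.0, atol=1e-9)

    def test_seed_determinism(self, profiles):
        cfg = GeneratorConfig(n_per_category=3, seed=9, n_actors=3)
        a = generate_stimulus_set(profiles, cfg)
        b = generate_stimulus_set(profiles, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.frames, sb.frames)

    def test_too_few_frames_rejected(self, profiles):
        with pytest.raises(ValueError, match="3 frames"):
            generate_stimulus_set(profiles, GeneratorConfig(n_frames=2, seed=0))

    def test_category_orderings(self, profiles):
        """Computed features of generated skeletons keep the reference
        between-category orderings (fear most flexed and contracted,
        neutral most static and least extended, anger drifting up)."""
        cfg = GeneratorConfig(n_per_category=100, n_actors=7, seed=17)
        table = build_feature_table(generate_stimulus_set(profiles, cfg))
        m = table.data.groupby(table.emotions).mean()
        others = [e for e in EMOTIONS if e != "fear"]
        assert all(
            m.loc["fear", "limb_angles"] < m.loc[e, "limb_angles"]
            for e in others
        )
        assert all(
            m.loc["fear", "limb_contraction"] < m.loc[e, "limb_contraction"]
            for e in others
        )
        non_neutral = [e for e in EMOTIONS if e != "neutral"]
        assert all(
            m.loc["neutral", "velocity"] < m.loc[e, "velocity"]
            for e in non_neutral
        )
        assert all(
            m.loc["neutral", "acceleration"] < m.loc[e, "acceleration"]
            for e in non_neutral
        )
        assert all(
            m.loc["neutral", "shoulder_ratio"] > m.loc[e, "shoulder_ratio"]
            for e in non_neutral
        )
        assert (
            m.loc["anger", "vertical_movement"]
            > m.loc["fear", "vertical_movement"]
        )


class TestRatingGenerator:
    def test_response_counts(self, small_stimulus_set):
        rt = generate_ratings(
            small_stimulus_set,
            RatingGeneratorConfig(n_participants=5, seed=0),
        )
        # participants x stimuli x 11 questions
        assert len(rt.data) == 5 * 16 * 11

    def test_default_design_counts(self, profiles):
        table = generate_feature_table(profiles, GeneratorConfig(seed=0))
        rt = generate_ratings(table, RatingGeneratorConfig(seed=0))
        assert len(rt.data) == 30 * 56 * 11

    def test_zero_noise_identity_perfect_agreement(self, small_stimulus_set):
        rt = generate_ratings(
            small_stimulus_set,
            RatingGeneratorConfig(
                n_participants=4, participant_noise_sd=0.0,
                confusion=_identity_confusion(), seed=3,
            ),
        )
        for q in rt.questions:
            wide = rt.pivot(q)
            assert (wide.nunique(axis=0) == 1).all()
        icc = stats.icc_absolute_agreement(rt.pivot("amount"))
        assert icc.icc_single == pytest.approx(1.0)
        assert icc.icc_average == pytest.approx(1.0)

    def test_happy_modal_response_is_happy(self, profiles):
        table = generate_feature_table(profiles, GeneratorConfig(seed=0))
        rt = generate_ratings(table, RatingGeneratorConfig(seed=11))
        wide = rt.pivot("emotion")
        happy_cols = [s for s in wide.columns
                      if rt.emotions[s] == "happiness"]
        responses = wide[happy_cols].to_numpy().ravel()
        values, counts = np.unique(responses, return_counts=True)
        assert values[counts.argmax()] == "happiness"
        rate = (responses == "happiness").mean()
        assert 0.70 < rate < 0.86  # around the 78% design rate

    def test_bad_confusion_rejected(self):
        bad = _identity_confusion()
        bad["anger"]["fear"] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            RatingGeneratorConfig(confusion=bad)

    def test_determinism_and_clipping(self, small_stimulus_set):
        cfg = RatingGeneratorConfig(n_participants=3, seed=21,
                                    participant_noise_sd=3.0)
        a = generate_ratings(small_stimulus_set, cfg)
        b = generate_ratings(small_stimulus_set, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
        for q in a.questions:
            if a.is_scale(q):
                vals = a.pivot(q).to_numpy()
                assert vals.min() >= 1.0 and vals.max() <= 7.0

    def test_csv_roundtrip(self, small_stimulus_set, tmp_path):
        rt = generate_ratings(small_stimulus_set,
                              RatingGeneratorConfig(n_participants=3, seed=2))
        rt.to_csv(tmp_path / "ratings.csv")
        back = rt.from_csv(tmp_path / "ratings.csv")
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), rt.data.reset_index(drop=True)
        )


class TestTimeCodedTables:
    def test_time_average_carries_no_category_signal(self):
        avg, tp = generate_time_coded_tables(seed=0, noise_sd=0.0)
        # with zero noise the time-averages are identical across categories
        assert np.allclose(avg.data.to_numpy().std(axis=0), 0.0, atol=1e-9)
        assert tp.data.shape == (56, 8 * 23)

    def test_confusion_rows_sum_to_one(self):
        for row in default_confusion().values():
            assert sum(row.values()) == pytest.approx(1.0)
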