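"""End-to-end orchestration: simulate → extract → RSA → ANOVA → classify.

A single :class:`PipelineConfig` (readable from a YAML file) drives every
stage; all randomness flows from one master seed through deterministic
per-stage subseeds, so a completed run is exactly reproducible. Artifacts
are plain CSV/JSON files in the output directory plus a ``manifest.json``
recording the config hash, seeds and produced files; re-running a
completed config is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, rsa, stats
from .features import FEATURE_NAMES, build_feature_table
from .pose import EMOTIONS, PoseFormatError, read_openpose_json
from .pose import StimulusSet
from .ratings import SCALE_QUESTIONS, RatingTable
from .synthetic import (
    GeneratorConfig,
    RatingGeneratorConfig,
    default_profiles,
    generate_ratings,
    generate_stimulus_set,
)

__all__ = ["PipelineConfig", "ConfigError", "DataError", "run_pipeline"]

log = logging.getLogger("emokin")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, in one declarative object."""

    mode: str = "synthetic"            # synthetic | pose_dir | ratings_file
    out_dir: str = "emokin_run"
    seed: int = 0
    pose_dir: str | None = None        # pose_dir mode: directory of stimuli
    ratings_file: str | None = None    # ratings_file mode: RatingTable CSV
    n_per_category: int = 14
    n_actors: int = 7
    n_frames: int = 25
    fps: int = 25
    skeleton_height: float = 300.0
    n_participants: int = 30
    participant_noise_sd: float = 0.5
    m_per_item_features: int = 9       # Bonferroni divisor, feature analysis
    m_per_item_ratings: int = 12       # Bonferroni divisor, rating analysis
    n_trees: int = 100
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: invalid YAML: {e}") from e
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown config fields {sorted(unknown)}; "
                f"known fields: {sorted(known)}"
            )
        return cls(**raw)

    def validate(self) -> None:
        problems = []
        if self.mode not in ("synthetic", "pose_dir", "ratings_file"):
            problems.append(f"mode: unknown mode {self.mode!r}")
        if self.mode == "pose_dir" and not self.pose_dir:
            problems.append("pose_dir: required in pose_dir mode")
        if self.mode == "ratings_file" and not self.ratings_file:
            problems.append("ratings_file: required in ratings_file mode")
        for fname in ("n_per_category", "n_actors", "n_frames", "fps",
                      "n_participants", "n_trees"):
            if getattr(self, fname) < 1:
                problems.append(f"{fname}: must be >= 1")
        if self.participant_noise_sd < 0:
            problems.append("participant_noise_sd: must be >= 0")
        if problems:
            raise ConfigError("invalid config: " + "; ".join(problems))

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "force"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _subseeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _load_pose_dir(pose_dir: str) -> StimulusSet:
    root = Path(pose_dir)
    meta_path = root / "metadata.csv"
    if not meta_path.exists():
        raise DataError(f"{root}: missing metadata.csv (stimulus manifest)")
    meta = pd.read_csv(meta_path)
    required = {"stimulus_id", "emotion", "actor_id", "filename"}
    if required - set(meta.columns):
        raise DataError(
            f"{meta_path}: needs columns {sorted(required)}"
        )
    sequences = []
    for _, row in meta.iterrows():
        path = root / row["filename"]
        try:
            sequences.append(
                read_openpose_json(
                    path, row["stimulus_id"], row["emotion"], row["actor_id"]
                )
            )
        except PoseFormatError as e:
            raise DataError(f"failed reading {path}: {e}") from e
    return StimulusSet(sequences)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages for one config and return the run directory.

    Stages that lack their input (e.g. no ratings in pose_dir mode) are
    skipped with a logged warning. A run directory whose manifest matches
    the config hash is returned untouched unless ``config.force``.
    """
    config.validate()
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    chash = config.content_hash()
    if manifest_path.exists() and not config.force:
        existing = json.loads(manifest_path.read_text())
        if existing.get("config_hash") == chash:
            log.info("run already complete for this config; skipping")
            return out
    out.mkdir(parents=True, exist_ok=True)
    seeds = _subseeds(config.seed, 4)
    artifacts: list[str] = []

    def save_csv(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(out / name, float_format="%.17g", **kw)
        artifacts.append(name)

    # --- stimuli -----------------------------------------------------------
    ratings = None
    stimuli = None
    if config.mode == "synthetic":
        gen = GeneratorConfig(
            n_per_category=config.n_per_category, n_actors=config.n_actors,
            n_frames=config.n_frames, fps=config.fps,
            skeleton_height=config.skeleton_height, seed=seeds[0],
        )
        stimuli = generate_stimulus_set(default_profiles(), gen)
        ratings = generate_ratings(
            stimuli,
            RatingGeneratorConfig(
                n_participants=config.n_participants,
                participant_noise_sd=config.participant_noise_sd,
                seed=seeds[1],
            ),
        )
        ratings.to_csv(out / "ratings.csv")
        artifacts.append("ratings.csv")
    elif config.mode == "pose_dir":
        stimuli = _load_pose_dir(config.pose_dir)
    else:  # ratings_file
        try:
            ratings = RatingTable.from_csv(config.ratings_file)
        except (OSError, KeyError, ValueError) as e:
            raise DataError(
                f"failed reading ratings {config.ratings_file}: {e}"
            ) from e

    # --- features ----------------------------------------------------------
    tables = {}
    if stimuli is not None:
        for mode in ("averaged", "time_preserving"):
            table = build_feature_table(stimuli, mode=mode)
            table.to_csv(out / f"features_{mode}.csv")
            artifacts += [f"features_{mode}.csv", f"features_{mode}.meta.json"]
            tables[mode] = table
    else:
        log.warning("no pose data; skipping feature extraction")

    # --- RSA ---------------------------------------------------------------
    feature_rdms: dict[str, rsa.RDM] = {}
    if "averaged" in tables:
        table = tables["averaged"]
        emotion_rdm = rsa.dummy_rdm(table.emotions, source="emotion")
        emotion_rdm.to_csv(out / "rdm_emotion.csv")
        artifacts += ["rdm_emotion.csv", "rdm_emotion.meta.json"]
        for feat in FEATURE_NAMES:
            feature_rdms[feat] = rsa.euclidean_rdm(
                table.data[feat], table.stimulus_ids, source=feat
            )
            feature_rdms[feat].to_csv(out / f"rdm_{feat}.csv")
            artifacts += [f"rdm_{feat}.csv", f"rdm_{feat}.meta.json"]
        second = rsa.second_level_matrix(
            {"emotion": emotion_rdm, **feature_rdms},
            m_per_item=config.m_per_item_features,
        )
        save_csv(second.tidy(), "second_level_features.csv", index=False)

    rating_rdm_map: dict[str, rsa.RDM] = {}
    if ratings is not None:
        rating_rdm_map = rsa.rating_rdms(ratings)
        emotion_rdm_r = rsa.dummy_rdm(
            ratings.emotions, source="emotion"
        )
        second_r = rsa.second_level_matrix(
            {"emotion": emotion_rdm_r, **rating_rdm_map},
            m_per_item=config.m_per_item_ratings,
        )
        save_csv(second_r.tidy(), "second_level_ratings.csv", index=False)
        if feature_rdms:
            cross_rows = []
            for q, qr in rating_rdm_map.items():
                for feat, fr in feature_rdms.items():
                    c = rsa.compare_rdms(qr, fr, config.m_per_item_ratings)
                    cross_rows.append(
                        {"rating": q, "feature": feat, "rho": c.rho,
                         "df": c.df, "p_raw": c.p_raw,
                         "p_bonferroni": c.p_bonferroni}
                    )
            save_csv(pd.DataFrame(cross_rows), "second_level_cross.csv",
                     index=False)
    else:
        log.warning("no ratings; skipping rating RSA, ICC and rating trees")

    # --- ANOVA + post-hocs -------------------------------------------------
    if "averaged" in tables:
        table = tables["averaged"]
        anova_rows, posthoc_rows = [], []
        for feat in FEATURE_NAMES:
            wide = _exemplar_by_emotion(table, feat)
            res = stats.rm_anova(wide)
            anova_rows.append(
                {"feature": feat, "F": res.F, "df1": res.df1, "df2": res.df2,
                 "p": res.p, "partial_eta_squared": res.partial_eta_squared,
                 "epsilon": res.epsilon, "corrected": res.corrected}
            )
            ph = stats.posthoc_bonferroni(wide).rows.assign(feature=feat)
            posthoc_rows.append(ph)
        save_csv(pd.DataFrame(anova_rows), "anova.csv", index=False)
        save_csv(pd.concat(posthoc_rows, ignore_index=True), "posthoc.csv",
                 index=False)

    # --- ICC ---------------------------------------------------------------
    if ratings is not None:
        icc_rows = []
        for q in SCALE_QUESTIONS:
            if q not in ratings.questions:
                continue
            res = stats.icc_absolute_agreement(ratings.pivot(q))
            icc_rows.append(
                {"question": q, "icc_single": res.icc_single,
                 "icc_average": res.icc_average}
            )
        save_csv(pd.DataFrame(icc_rows), "icc.csv", index=False)

    # --- classification ----------------------------------------------------
    reports = {}
    wanted: list[tuple[str, object]] = []
    if "averaged" in tables:
        wanted.append(("features_averaged", tables["averaged"]))
    if "time_preserving" in tables:
        wanted.append(("features_time_preserving", tables["time_preserving"]))
    if ratings is not None:
        wanted += [("ratings_nine", ratings), ("ratings_six", ratings)]
    if stimuli is not None:
        wanted += [("bodyside_three", stimuli), ("joints_fourteen", stimuli)]
    for i, (name, src) in enumerate(wanted):
        pset = classify.build_predictor_set(src, name)
        reports[name] = classify.fit_bagged_trees(
            pset, n_trees=config.n_trees, seed=seeds[2] + i
        )
    if reports:
        (out / "classifier_reports.json").write_text(
            json.dumps({n: r.to_dict() for n, r in reports.items()}, indent=2)
        )
        artifacts.append("classifier_reports.json")
        if len(reports) > 1:
            save_csv(classify.compare_models(reports), "model_comparison.csv")

    manifest = {
        "config_hash": chash,
        "config": asdict(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_stimuli": len(stimuli) if stimuli is not None else 0,
        "n_rdms": len(feature_rdms) + (1 if feature_rdms else 0),
        "artifacts": sorted(set(artifacts)),
        "versions": _versions(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out


def _exemplar_by_emotion(table, feature: str) -> pd.DataFrame:
    """Exemplar-index x emotion wide table for the repeated-measures ANOVA.

    Exemplars are paired across categories by their within-category index
    (the study's pairing of the 14 videos per category is not recoverable,
    so index pairing is the fixed convention here).
    """
    from .evaluation import anova_by_emotion

    try:
        wide = anova_by_emotion(table, feature)
    except ValueError as e:
        raise DataError(str(e)) from e
    return wide[[e for e in EMOTIONS if e in wide.columns]]


def _versions() -> dict[str, str]:
    import pingouin
    import scipy
    import sklearn

    from . import __version__

    return {
        "emokin": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pingouin": pingouin.__version__,
    }
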