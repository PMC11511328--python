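"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
train -> evaluate -> explain -> stats, with derived sub-seeds and a
reproducible artifact directory."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from speckleid import classify, explain as explain_mod, stats as stats_mod
from speckleid.features import FEATURE_NAMES, extract_features
from speckleid.preprocess import (apply_normalizer, crop_dataset,
                                  fit_normalizer, split_train_test)
from speckleid.select import apply_mask, collinearity_filter, remove_outliers
from speckleid.simulate import (Dataset, OpticalConfig, SimConfig,
                                build_dataset, default_catalog)

__all__ = ["PipelineConfig", "run_pipeline", "extract_feature_table"]

logger = logging.getLogger("speckleid.pipeline")


@dataclass
class PipelineConfig:
    """Single knob set for the whole run; every stage gets a derived sub-seed."""

    # simulate
    samples_per_drug: int = 4
    videos_per_sample: int = 3
    frames_per_video: int = 100
    frame_height_px: int = 1088
    frame_width_px: int = 1456
    grain_size_px: float = 3.0
    temporal_mixing: float = 0.3
    session_gain_sd: float = 0.03
    mean_intensity_scale: float = 120.0
    # preprocess
    crop_size: int = 224
    split_fraction: float = 0.8
    split_unit: str = "frame"
    # select
    lof_fraction: float = 0.10
    lof_k: int = 20
    pcc_threshold: float = 0.9
    # classify
    model_family: str = "mlp"
    grid: dict = field(default_factory=dict)
    cv_folds: int = 10
    n_boot: int = 1000
    # explain
    shap_background: int = 100
    shap_samples: int = 50
    shap_permutations: int = 50
    # stats
    stats_unit: str = "image"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def sub_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big")


def extract_feature_table(dataset: Dataset, normalizer=None) -> pd.DataFrame:
    """Feature rows (one per frame) with drug/sample/video/frame metadata."""
    rows = []
    for fr in dataset.frames:
        img = fr.image
        if normalizer is not None:
            img = apply_normalizer(normalizer, img, fr.drug_name)
        feats = extract_features(img)
        rows.append({"drug": fr.drug_name, "sample": fr.sample_id,
                     "video": fr.video_id, "frame": fr.frame_index,
                     "day": fr.day, **feats})
    df = pd.DataFrame(rows)
    return df[["drug", "sample", "video", "frame", "day"] + list(FEATURE_NAMES)]


class _StageTracker:
    def __init__(self) -> None:
        self.current = "init"

    def __call__(self, name: str) -> None:
        self.current = name
        logger.info("stage %s", name)


def run_pipeline(config: PipelineConfig, out_dir: str,
                 dataset: Dataset | None = None) -> dict:
    """Execute every stage and write artifacts under ``out_dir``.

    Returns a summary dict (also written as ``run.json``).  A pre-built
    dataset can be supplied to skip simulation.
    """
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    summary: dict = {"config": config.to_dict(),
                     "config_hash": config.config_hash()}
    _stage = _StageTracker()

    try:
        if dataset is None:
            _stage("simulate")
            sim = SimConfig(grain_size_px=config.grain_size_px,
                            temporal_mixing=config.temporal_mixing,
                            session_gain_sd=config.session_gain_sd,
                            mean_intensity_scale=config.mean_intensity_scale,
                            seed=config.sub_seed("simulate"))
            cfg = OpticalConfig(frame_height_px=config.frame_height_px,
                                frame_width_px=config.frame_width_px)
            dataset = build_dataset(default_catalog(),
                                    samples_per_drug=config.samples_per_drug,
                                    videos_per_sample=config.videos_per_sample,
                                    frames_per_video=config.frames_per_video,
                                    sim=sim, cfg=cfg)
        summary["n_frames"] = len(dataset)

        _stage("preprocess")
        cropped = crop_dataset(dataset, config.crop_size)
        split = split_train_test(cropped, fraction=config.split_fraction,
                                 seed=config.sub_seed("split"),
                                 unit=config.split_unit)
        normalizer = fit_normalizer(split.train)
        with open(os.path.join(out_dir, "normalizer.json"), "w") as fh:
            json.dump({"means": normalizer.means, "stds": normalizer.stds},
                      fh, indent=2)
        summary["n_train"] = len(split.train)
        summary["n_test"] = len(split.test)

        _stage("extract")
        train_df = extract_feature_table(split.train, normalizer)
        test_df = extract_feature_table(split.test, normalizer)
        train_df.assign(split="train").pipe(
            lambda a: pd.concat([a, test_df.assign(split="test")])
        ).to_csv(os.path.join(out_dir, "features.csv"), index=False,
                 float_format="%.12g")

        _stage("select")
        feat_cols = list(FEATURE_NAMES)
        kept_rows = remove_outliers(train_df[feat_cols],
                                    fraction=config.lof_fraction,
                                    k=config.lof_k)
        train_df = train_df.loc[kept_rows.index]
        summary["n_train_after_lof"] = len(train_df)
        mask = collinearity_filter(train_df[feat_cols],
                                   threshold=config.pcc_threshold,
                                   seed=config.sub_seed("pcc"))
        summary["n_features_kept"] = len(mask.kept)
        with open(os.path.join(out_dir, "mask.json"), "w") as fh:
            json.dump({"kept": mask.kept, "threshold": mask.threshold,
                       "dropped_pairs": mask.dropped_pairs}, fh, indent=2)

        _stage("train")
        model_cfg = classify.ModelConfig(family=config.model_family,
                                         grid=dict(config.grid),
                                         cv_folds=config.cv_folds,
                                         seed=config.sub_seed("train"))
        X_train = apply_mask(train_df, mask)
        y_train = train_df["drug"].to_numpy()
        best = classify.grid_search(X_train, y_train, model_cfg)
        model = classify.train(best, X_train, y_train,
                               family=config.model_family,
                               seed=config.sub_seed("train"))

        _stage("evaluate")
        X_test = apply_mask(test_df, mask)
        y_test = test_df["drug"].to_numpy()
        report = classify.evaluate(model, X_test, y_test,
                                   n_boot=config.n_boot,
                                   seed=config.sub_seed("evaluate"))
        summary["metrics"] = report.metrics
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)

        _stage("explain")
        rng = np.random.default_rng(config.sub_seed("explain"))
        bg_idx = rng.choice(len(X_train),
                            size=min(config.shap_background, len(X_train)),
                            replace=False)
        s_idx = rng.choice(len(X_test),
                           size=min(config.shap_samples, len(X_test)),
                           replace=False)
        shap = explain_mod.shapley_values(
            lambda A: model.predict_proba(A),
            X_train.iloc[bg_idx], X_test.iloc[s_idx],
            n_permutations=config.shap_permutations,
            seed=config.sub_seed("explain"))
        importance = explain_mod.global_importance(shap)
        importance.rename("mean_abs_phi").to_csv(
            os.path.join(out_dir, "shap_importance.csv"))

        _stage("stats")
        images_by_drug = {d: [fr.image for fr in split.test.frames
                              if fr.drug_name == d]
                          for d in split.test.drug_names}
        if config.stats_unit == "image":
            groups = [np.array([np.asarray(im, dtype=float).mean()
                                for im in imgs])
                      for imgs in images_by_drug.values()]
        else:
            groups = [np.concatenate([np.asarray(im, dtype=float).ravel()
                                      for im in imgs])
                      for imgs in images_by_drug.values()]
        names = list(images_by_drug)
        F, p = stats_mod.anova_oneway(groups)
        tukey = stats_mod.tukey_hsd(groups, alpha=0.01, names=names)
        summary["anova"] = {"F": F, "p": p}
        with open(os.path.join(out_dir, "stats.json"), "w") as fh:
            json.dump({"anova": {"F": F, "p": p},
                       "tukey": tukey.to_dict(orient="records")}, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {_stage.current!r}: {exc}") from exc

    summary["elapsed_s"] = time.time() - t0
    with open(os.path.join(out_dir, "run.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
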