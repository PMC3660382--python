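"""End-to-end orchestration: extract -> rank -> SFS -> dual validation.

A run reads either an image directory (each image with a sidecar ``.roi``
vertex file) or a precomputed feature CSV, and writes every intermediate —
feature table, ranking, SFS trace, metric reports — into a run directory.
Each JSON artifact records the configuration hash and master seed that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import SvmConfig
from .evaluation import half_and_half_eval, loocv_eval, report_table
from .feature_selection import SfsConfig, rank_features, sfs_curve, trace_to_frame
from .roi_imaging import extract_subimage, load_image, read_roi
from .synthetic import (CP_PARAMS, PC_PARAMS, TextureClassParams,
                        cohort_feature_table)
from .texture_features import FeatureConfig, extract_all, feature_table

log = logging.getLogger("eustex")


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of an end-to-end run, JSON-round-trippable."""

    grey_levels: int = 64
    glcm_distances: tuple[int, ...] = (1, 2)
    wavelet: str = "db4"
    select_m: int = 25
    sfs_mode: str = "ranked"
    sfs_trials: int = 20
    eval_trials: int = 200
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    svm_gamma: float | None = None
    seed: int = 0
    images_dir: str | None = None
    features_csv: str | None = None
    out_dir: str = "run"

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(grey_levels=self.grey_levels,
                             glcm_distances=tuple(self.glcm_distances),
                             wavelet=self.wavelet)

    def svm_config(self) -> SvmConfig:
        return SvmConfig(kernel=self.svm_kernel, C=self.svm_c,
                         gamma=self.svm_gamma)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if "glcm_distances" in data:
            data["glcm_distances"] = tuple(data["glcm_distances"])
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def load_cohort_images(images_dir: str | Path,
                       config: FeatureConfig) -> pd.DataFrame:
    """Feature table from a directory of images with sidecar ROI files.

    Expects a ``manifest.csv`` with columns ``case_id,image,roi,label``;
    paths are relative to the directory.
    """
    images_dir = Path(images_dir)
    manifest = pd.read_csv(images_dir / "manifest.csv")
    subs, labels, ids = [], [], []
    for _, row in manifest.iterrows():
        image = load_image(images_dir / row["image"])
        roi = read_roi(images_dir / row["roi"], image)
        subs.append(extract_subimage(image, roi))
        labels.append(int(row["label"]))
        ids.append(str(row["case_id"]))
    return feature_table(subs, labels, case_ids=ids, config=config)


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"config_hash": config.hash(), "seed": config.seed, **payload}
    path.write_text(json.dumps(payload, indent=2))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full study on one cohort; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc = config.feature_config()

    stage = "extract"
    try:
        if config.features_csv is not None:
            table = pd.read_csv(config.features_csv)
        elif config.images_dir is not None:
            table = load_cohort_images(config.images_dir, fc)
        else:
            raise ValueError("config needs images_dir or features_csv")
        table.to_csv(out / "features.csv", index=False)

        stage = "rank"
        ranking = rank_features(table, m=config.select_m)
        _write_json(out / "ranking.json",
                    {"scores": ranking.scores,
                     "order": list(ranking.order),
                     "selected": list(ranking.selected)}, config)

        stage = "sfs"
        sfs_cfg = SfsConfig(n_trials=config.sfs_trials,
                            seed=config.seed + 1_000_003,
                            svm=config.svm_config(), mode=config.sfs_mode)
        trace = sfs_curve(table, ranking, sfs_cfg)
        _write_json(out / "sfs_trace.json",
                    {"steps": trace_to_frame(trace).to_dict("records"),
                     "optimum_k": trace.optimum_k,
                     "optimum_ccr": trace.optimum_ccr}, config)

        stage = "evaluate"
        subset = trace.optimum_features
        half = half_and_half_eval(table, subset, n_trials=config.eval_trials,
                                  seed=config.seed,
                                  svm_config=config.svm_config())
        loo = loocv_eval(table, subset, svm_config=config.svm_config())
        _write_json(out / "report.json",
                    {"features": subset,
                     "half_and_half": {"mean": half.mean, "se": half.se,
                                       "n_trials": half.n_trials,
                                       "n_undefined": half.n_undefined},
                     "leave_one_out": {"mean": loo.mean}}, config)
        (out / "report.txt").write_text(report_table(half, loo) + "\n")
        _write_json(out / "manifest.json",
                    {"artifacts": ["features.csv", "ranking.json",
                                   "sfs_trace.json", "report.json",
                                   "report.txt"],
                     "config": dataclasses.asdict(config)}, config)
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}")
    log.info("run complete: optimum k=%d, half-and-half accuracy %.2f%%",
             trace.optimum_k, half.mean["accuracy"])
    return out


def simulate_cohort_dir(out_dir: str | Path, n_pc: int, n_cp: int,
                        size: tuple[int, int] = (64, 64), seed: int = 0,
                        params_pc: TextureClassParams = PC_PARAMS,
                        params_cp: TextureClassParams = CP_PARAMS) -> Path:
    """Write a synthetic cohort as PNGs + full-frame ROI files + manifest."""
    from .roi_imaging import save_image
    from .synthetic import generate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, labels, ids = generate_cohort(params_pc, params_cp, n_pc, n_cp,
                                          size=size, seed=seed)
    rows = []
    for img, label, cid in zip(images, labels, ids):
        save_image(img, out / f"{cid}.png")
        h, w = img.shape
        roi = f"0,0\n0,{w-1}\n{h-1},{w-1}\n{h-1},0\n"
        (out / f"{cid}.roi").write_text(roi)
        rows.append({"case_id": cid, "image": f"{cid}.png",
                     "roi": f"{cid}.roi", "label": int(label)})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
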