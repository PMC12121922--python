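"""End-to-end pipeline: colorize -> segment -> features -> select -> evaluate.

Configured from YAML (or a :class:`PipelineConfig` built in Python), the
pipeline persists every intermediate (masks, feature CSV, selection JSON,
metrics report) so stages can be inspected or resumed, and a single global
seed propagates to every stochastic stage for bitwise reproducibility.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, features, phantoms, preprocess, segmentation, selection
from .chaos import EmbeddingConfig
from .segmentation import FCMConfig
from .texture import GLCMConfig

__all__ = ["PipelineConfig", "run_pipeline", "simulate_dataset", "load_dataset"]

log = logging.getLogger("thermocad")

SELECTORS = {
    "nsga3": selection.nsga3_select,
    "ga": selection.ga_select,
    "pso": selection.pso_select,
    "de": selection.de_select,
}


@dataclass
class PipelineConfig:
    image_dir: str = "images"
    labels_csv: str = "labels.csv"
    out_dir: str = "out"
    seed: int = 0
    fcm_k: int = 4
    fcm_m: float = 2.0
    glcm_levels: int = 16
    emb_dim: int = 3
    emb_delay: int = 2
    series_order: str = "row_major"
    selector: str = "nsga3"
    folds: int = 10
    save_images: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def simulate_dataset(n_per_class: int, seed: int, out_dir: str | Path) -> Path:
    """Write a balanced phantom cohort (PNG images + labels.csv) to disk."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    images, labels, _ = phantoms.generate_dataset(n_per_class, seed=seed)
    rows = []
    for img in images:
        fname = f"{img.id}.png"
        preprocess.save_image(img.pixels, out / "images" / fname)
        rows.append({"filename": fname, "label": labels[img.id]})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    return out


def load_dataset(image_dir: str | Path, labels_csv: str | Path):
    labels = pd.read_csv(labels_csv)
    images = []
    for fname in labels["filename"]:
        path = Path(image_dir) / fname
        if not path.exists():
            raise FileNotFoundError(f"preprocess stage: missing image file {path}")
        images.append(preprocess.load_image(path, id=os.path.splitext(fname)[0]))
    y = pd.Series(labels["label"].to_numpy(),
                  index=[os.path.splitext(f)[0] for f in labels["filename"]])
    return images, y


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order, persisting intermediates under ``out_dir``.

    Returns a dict with the feature table, selection result and evaluation
    reports.  A stage failure raises with a stage-tagged message; artifacts
    written before the failure are retained.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    def stage(name):
        log.info("stage %-10s (t=%.1fs)", name, time.perf_counter() - t_start)

    stage("load")
    try:
        images, labels = load_dataset(cfg.image_dir, cfg.labels_csv)
    except Exception as exc:
        raise RuntimeError(f"[preprocess] failed to load dataset: {exc}") from exc

    stage("features")
    fcm = FCMConfig(k=cfg.fcm_k, m=cfg.fcm_m, seed=cfg.seed)
    glcm = GLCMConfig(levels=cfg.glcm_levels)
    emb = EmbeddingConfig(dim=cfg.emb_dim, delay=cfg.emb_delay, series_order=cfg.series_order)
    try:
        table = features.feature_table(images, fcm=fcm, glcm=glcm, emb=emb)
    except Exception as exc:
        raise RuntimeError(f"[features] feature extraction failed: {exc}") from exc
    table.to_csv(out / "features.csv")

    if cfg.save_images:
        stage("masks")
        for img in images:
            seg = segmentation.segment_image(img, fcm)
            preprocess.save_image(seg.roi_mask, out / f"{img.id}_roi.png")

    stage("select")
    y = labels.loc[table.index]
    try:
        sel = SELECTORS[cfg.selector](table, classify.encode_labels(y), seed=cfg.seed)
    except KeyError as exc:
        raise RuntimeError(f"[select] unknown selector {cfg.selector!r}") from exc
    with open(out / "selection.json", "w") as fh:
        json.dump({
            "method": sel.method, "chosen_subset": sel.chosen_subset,
            "best_scalar": sel.best_scalar, "history": sel.history,
            "pareto": [{"features": [n for n, b in zip(table.columns, bits) if b],
                        "error": o.error, "nf_frac": o.nf_frac}
                       for bits, o in sel.pareto],
            "runtime_s": sel.runtime,
        }, fh, indent=2)

    stage("evaluate")
    subsets = {
        "texture_only": [c for c in features.TEXTURE_FEATURE_NAMES],
        "nonlinear_only": [c for c in features.CHAOS_FEATURE_NAMES],
        "combined_selected": sel.chosen_subset,
    }
    try:
        reports = classify.run_experiment(table, y, subsets, k=cfg.folds, seed=cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"[evaluate] classification failed: {exc}") from exc
    summary = pd.concat({k: r.summary() for k, r in reports.items()}, names=["regime", "classifier"])
    summary.to_csv(out / "metrics.csv")
    with open(out / "report.json", "w") as fh:
        json.dump({regime: {clf: rep.mean_metrics(clf) for clf in rep.fold_counts}
                   for regime, rep in reports.items()}, fh, indent=2)
    stage("done")
    return {"features": table, "selection": sel, "reports": reports, "summary": summary}
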