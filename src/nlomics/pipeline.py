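"""End-to-end orchestration: simulate → features → screen → stats → classify.

The pipeline mirrors the study workflow: per-ROI depth stacks are segmented
(collagen via Frangi + Rényi threshold on the pooled ROI histogram, TPEF via
8-bit rescale + Rényi), conventional and radiomic features are extracted per
frame, radiomic features are screened by train/test KDE overlap, conventional
features are significance-tested, the radiomics-vs-conventional Pearson
matrix is computed, and a Monte-Carlo stacked ensemble is trained on the
training subject and evaluated on the held-out subject.

Every stage is deterministic given the config (all randomness flows from the
config seed) and each run directory records the config and its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import harmonize
from .conventional import FEATURE_NAMES, conventional_feature_vector
from .fibers import trace_fibers
from .image_io import TwoChannelStack, write_stack
from .preprocess import segment_collagen_pipeline, segment_tpef_pipeline
from .radiomics import compute_feature_panel, radiomics_preprocess
from .synthetic import (DEFAULT_PIXEL_SIZE_UM, DEFAULT_SIZE_PX,
                        default_presets, generate_dataset)

log = logging.getLogger("nlomics")

META_COLUMNS = ("frame", "class", "roi", "subject", "split", "seed")


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    seed: int = 0
    # synthetic dataset
    n_per_class_per_roi: int = 15
    n_rois: int = 2
    size_px: int = DEFAULT_SIZE_PX
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    roi_jitter_sd: float = 0.08
    # preprocessing
    frangi_scales_px: tuple = (1.8, 4.9, 8.0)
    renyi_order: float = 1.0
    # fiber tracer
    min_fiber_length_px: float = 15.0
    merge_angle_deg: float = 30.0
    # radiomics
    radiomics_enabled: bool = True
    glcm_distance: int = 1
    peak_radius_px: float = 3.0
    # screening
    screen_threshold: float = 0.75
    # machine learning
    n_folds: int = 100
    validate_fraction: float = 0.2
    redundancy_threshold: float = 0.95
    n_selected_features: int = 20

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "frangi_scales_px" in data:
            data["frangi_scales_px"] = tuple(data["frangi_scales_px"])
        return cls(**data)

    @property
    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate(config: RunConfig):
    """Generate the synthetic labeled dataset declared by the config."""
    return generate_dataset(
        presets=default_presets(),
        n_per_class_per_roi=config.n_per_class_per_roi,
        n_rois=config.n_rois,
        seed=config.seed,
        size_px=config.size_px,
        pixel_size_um=config.pixel_size_um,
        roi_jitter_sd=config.roi_jitter_sd,
    )


def extract_features(stacks: dict[str, TwoChannelStack], manifest: pd.DataFrame,
                     config: RunConfig) -> pd.DataFrame:
    """Per-frame conventional (and optionally radiomic) feature table.

    Collagen/TPEF segmentations use per-ROI pooled-histogram thresholds;
    radiomics requantization uses one linear map per modality across all
    ROIs, as the protocol requires.
    """
    rows = []
    frame_pairs_all = []  # for dataset-wide radiomics preprocessing
    order = []
    for roi_id, stack in stacks.items():
        shg_stack = stack.channel("SHG")
        tpef_stack = stack.channel("TPEF")
        t0 = time.time()
        shg_bin = segment_collagen_pipeline(shg_stack, config.frangi_scales_px,
                                            config.renyi_order)
        tpef_bin = segment_tpef_pipeline(tpef_stack, config.renyi_order)
        log.info("segmented %s (%d frames) in %.1fs", roi_id, len(stack),
                 time.time() - t0)
        roi_rows = manifest[manifest["roi"] == roi_id]
        for i, (_, meta) in enumerate(roi_rows.iterrows()):
            fibers = trace_fibers(shg_bin[i], stack.pixel_size_um,
                                  config.min_fiber_length_px,
                                  config.merge_angle_deg)
            feats = conventional_feature_vector(
                shg_stack[i], tpef_stack[i], shg_bin[i], tpef_bin[i], fibers)
            row = {k: meta[k] for k in ("frame", "class", "roi", "subject", "seed")}
            row.update(feats)
            rows.append(row)
            frame_pairs_all.append((shg_stack[i], tpef_stack[i]))
            order.append(meta["frame"])
    table = pd.DataFrame(rows).set_index("frame", drop=False)

    if config.radiomics_enabled:
        prepared, skip_log = radiomics_preprocess(frame_pairs_all)
        for entry in skip_log:
            log.warning("radiomics preprocessing: %s", entry)
        rad_rows = {}
        for frame_id, pair in zip(order, prepared):
            if pair is None:
                continue
            feats = {}
            for img in pair:
                keyed, _ = compute_feature_panel(img, config.glcm_distance,
                                                 config.peak_radius_px)
                feats.update(keyed)
            rad_rows[frame_id] = feats
        rad_table = pd.DataFrame.from_dict(rad_rows, orient="index")
        table = table.join(rad_table)
    return table.reset_index(drop=True)


def tag_splits(table: pd.DataFrame, train_subject: str = "S1") -> pd.DataFrame:
    """Tag frames of the training pseudo-subject as train, the rest as test."""
    table = table.copy()
    table["split"] = np.where(table["subject"] == train_subject, "train", "test")
    return table


def radiomic_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if "::" in c]


def conventional_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if c in table.columns]


def significance_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Kruskal–Wallis across classes and healthy-vs-pathological rank-sum
    for each conventional feature."""
    records = []
    healthy = table["class"] == "muscle"
    for col in conventional_columns(table):
        vals = table[col]
        groups = [vals[table["class"] == c].dropna().to_numpy()
                  for c in sorted(table["class"].unique())]
        try:
            h, p_kw = harmonize.kruskal_wallis(*groups)
        except ValueError:
            h, p_kw = float("nan"), float("nan")
        try:
            w, p_rs = harmonize.ranksum(vals[healthy].dropna(),
                                        vals[~healthy].dropna())
        except ValueError:
            w, p_rs = float("nan"), float("nan")
        records.append({"feature": col, "kw_H": h, "kw_p": p_kw,
                        "kw_significant": bool(p_kw < 0.05),
                        "ranksum_W": w, "ranksum_p": p_rs,
                        "ranksum_significant": bool(p_rs < 0.05)})
    return pd.DataFrame(records)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages and write artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    config.to_yaml(out / "config.yaml")
    stamp = {"config_hash": config.hash}

    stacks, manifest, _ = simulate(config)
    manifest.to_csv(out / "manifest.csv", index=False)
    tiff_dir = out / "images"
    tiff_dir.mkdir(exist_ok=True)
    for roi_id, stack in stacks.items():
        write_stack(tiff_dir / f"{roi_id}.tif", stack)

    table = tag_splits(extract_features(stacks, manifest, config))
    table.to_csv(out / "features.csv", index=False)

    stats = significance_tests(table)
    stats.to_csv(out / "stats.csv", index=False)

    rad_cols = radiomic_columns(table)
    report: dict = dict(stamp)
    if rad_cols:
        screen = harmonize.screen_features(table, config.screen_threshold,
                                           feature_columns=rad_cols)
        pd.DataFrame({"overlap": screen.overlaps, "kept": screen.kept}
                     ).to_csv(out / "screen.csv")
        kept = screen.kept_features
        sig_conv = stats.loc[stats["kw_significant"], "feature"].tolist()
        if kept and sig_conv:
            pearson = harmonize.pearson_matrix(table[sig_conv], table[kept])
            pearson.to_csv(out / "pearson.csv")
    else:
        kept = []
    ml_features = kept if kept else conventional_columns(table)

    train = table[table["split"] == "train"]
    test = table[table["split"] == "test"]
    labels = sorted(table["class"].unique())
    mc = clf.run_monte_carlo(
        train[ml_features], train["class"].to_numpy(),
        n_folds=config.n_folds, validate_fraction=config.validate_fraction,
        seed=config.seed,
        config=clf.EnsembleConfig(config.redundancy_threshold,
                                  config.n_selected_features))
    reports = clf.evaluate_on_test(mc.models, test[ml_features],
                                   test["class"].to_numpy(), labels)
    report.update({
        "n_frames": int(len(table)),
        "features_used": ml_features,
        "n_radiomic_kept": len(kept),
        "cv_accuracy_mean": mc.accuracy_mean,
        "cv_accuracy_sd": mc.accuracy_sd,
        "fold_accuracies": mc.fold_accuracies.tolist(),
        "test_multiclass_accuracy": reports["multiclass"].accuracy,
        "test_multiclass_matrix": reports["multiclass"].matrix.tolist(),
        "test_multiclass_sensitivity": reports["multiclass"].sensitivity,
        "test_binary_accuracy": reports["binary"].accuracy,
        "test_binary_matrix": reports["binary"].matrix.tolist(),
        "test_binary_specificity": reports["binary"].specificity,
        "weight_summary": mc.weight_summary().to_dict(),
    })
    (out / "report.json").write_text(json.dumps(report, indent=2))
    mc.weight_summary().to_csv(out / "feature_weights.csv")
    return out
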