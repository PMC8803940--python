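"""End-to-end desk-scale demonstration run.

``run_demo`` exercises the whole pipeline on synthetic data: it generates a
phantom training pool and a motion study, trains the two networks at desk
geometry, segments every study acquisition with both the two-stage deep
pipeline ("deepseg") and the probabilistic-atlas baseline ("atlas"),
evaluates head-motion reliability pairs, aggregates per-region metrics, runs
the nonparametric method comparisons with Benjamini-Hochberg correction, and
writes all tables plus the trained models.  Fully reproducible given a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import AtlasSegmenter
from .core_io import (
    LabelMask,
    LabelScheme,
    Volume,
    conform,
    default_scheme,
    normalize_intensity,
)
from .cropnet import (
    CropConfig,
    CropNet,
    CropTrainConfig,
    bbox_target,
    crop,
    finalize_bbox,
    predict_box,
    train_cropnet,
)
from .evalrel import (
    METRICS,
    aggregate,
    bh_adjust,
    build_pairs,
    compare_methods,
    evaluate_pairs,
    stat_results_frame,
)
from .geometry import DESK_SCALE, Geometry
from .phantom import PhantomSpec, generate_phantom, generate_study
from .segnet import SegNet, SegTrainConfig, predict, train_segnet

DEEP_METHOD = "deepseg"
ATLAS_METHOD = "atlas"


@dataclass
class DemoConfig:
    """Resolved configuration of a demonstration run."""

    seed: int = 7
    n_subjects: int = 12
    n_train: int = 20
    n_val: int = 3
    n_heldout: int = 4
    crop_epochs: int = 40
    seg_epochs: int = 7
    seg_base_channels: int = 8
    geometry: Geometry = DESK_SCALE


@dataclass
class DemoResult:
    out_dir: Path
    config: DemoConfig
    roster: pd.DataFrame
    region_metrics: pd.DataFrame
    summary: pd.DataFrame
    stats: pd.DataFrame
    recovery: dict
    crop_model: CropNet
    seg_model: SegNet

    def mean_dsc_by_pairing(self, method: str = DEEP_METHOD) -> pd.Series:
        rows = self.region_metrics
        sel = rows[rows["method"] == method]
        return sel.groupby("pairing_type")["dsc"].mean().sort_index()


def _true_center_box(mask: LabelMask, crop_cfg: CropConfig):
    """Fixed-size box centered on the mask-derived tight box (training-time
    cropping, where the reference mask is available)."""
    tight = bbox_target(mask)
    vec = tight.as_vector() * crop_cfg.downsample_factor
    return finalize_bbox(vec, crop_cfg, mask.shape)


def _foreground_dice(truth: LabelMask, pred: LabelMask) -> float:
    """Mean Dice over the non-Unknown regions present in the truth."""
    from .evalrel import dsc as _dsc

    vals = []
    for rid in truth.present_labels():
        if rid == truth.scheme.unknown_id:
            continue
        vals.append(_dsc(truth.labels == rid, pred.labels == rid))
    return float(np.nanmean(vals))


def run_demo(
    out_dir: str | Path,
    seed: int = 7,
    config: DemoConfig | None = None,
    log_progress=None,
) -> DemoResult:
    """Run the full desk-scale study; see the module docstring."""
    cfg = config or DemoConfig(seed=seed)
    cfg.seed = seed
    geometry = cfg.geometry
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    say = log_progress or (lambda *_: None)

    root = np.random.SeedSequence(seed)
    (s_phantom, s_crop, s_seg, s_study) = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    ]
    scheme = default_scheme()
    crop_cfg = CropConfig.from_geometry(geometry)

    # ---- training pool --------------------------------------------------
    say("generating training phantoms")
    n_total = cfg.n_train + cfg.n_val + cfg.n_heldout
    pool = []
    for i in range(n_total):
        vol, mask = generate_phantom(
            PhantomSpec(shape=tuple(geometry.conform_shape), seed=s_phantom + i),
            scheme,
        )
        pool.append((normalize_intensity(conform(vol, geometry)), mask))
    train = pool[: cfg.n_train]
    val = pool[cfg.n_train : cfg.n_train + cfg.n_val]
    heldout = pool[cfg.n_train + cfg.n_val :]

    # ---- stage 1: crop network -----------------------------------------
    say("training crop network")
    crop_pairs = [(v, bbox_target(m)) for v, m in train]
    crop_val = [(v, bbox_target(m)) for v, m in val]
    crop_log: list = []
    crop_model = train_cropnet(
        crop_pairs, crop_val,
        CropTrainConfig(max_epochs=cfg.crop_epochs, seed=s_crop),
        geometry=geometry, log=crop_log,
    )

    # ---- stage 2: segmentation network ----------------------------------
    say("training segmentation network")
    cropped_train = [
        (crop(v, _true_center_box(m, crop_cfg)), crop(m, _true_center_box(m, crop_cfg)))
        for v, m in train
    ]
    cropped_val = [
        (crop(v, _true_center_box(m, crop_cfg)), crop(m, _true_center_box(m, crop_cfg)))
        for v, m in val
    ]
    seg_log: list = []
    seg_model = train_segnet(
        cropped_train, cropped_val,
        SegTrainConfig(
            max_epochs=cfg.seg_epochs, seed=s_seg,
            base_channels=cfg.seg_base_channels,
        ),
        geometry=geometry, n_classes=scheme.n_classes, log=seg_log,
    )

    # ---- held-out recovery ----------------------------------------------
    say("evaluating held-out phantoms")
    diag = float(np.linalg.norm(crop_cfg.fixed_lengths))
    center_errors, dices = [], []
    for v, m in heldout:
        box = predict_box(crop_model, v, crop_cfg)
        true_box = _true_center_box(m, crop_cfg)
        err = float(
            np.linalg.norm(np.asarray(box.center) - np.asarray(true_box.center))
        )
        center_errors.append(err)
        pred_mask = predict(
            v, crop_model, seg_model, geometry=geometry, scheme=scheme,
            pre_conformed=True,
        )
        dices.append(_foreground_dice(m, pred_mask))
    recovery = {
        "box_diagonal_voxels": diag,
        "center_errors_voxels": center_errors,
        "mean_center_error_voxels": float(np.mean(center_errors)),
        "heldout_foreground_dice": dices,
        "mean_heldout_foreground_dice": float(np.mean(dices)),
        "crop_epochs_run": len(crop_log),
        "seg_epochs_run": len(seg_log),
    }

    # ---- motion study ----------------------------------------------------
    say("generating motion study")
    roster_base, records = generate_study(
        cfg.n_subjects, seed=s_study, geometry=geometry, scheme=scheme
    )
    atlas = AtlasSegmenter().fit(train)
    masks: dict[tuple[str, str], LabelMask] = {}
    say("segmenting study records")
    for rec in records:
        conformed = normalize_intensity(conform(rec.volume, geometry))
        masks[(DEEP_METHOD, rec.record_id)] = predict(
            rec.volume, crop_model, seg_model, geometry=geometry, scheme=scheme
        )
        masks[(ATLAS_METHOD, rec.record_id)] = atlas.predict(conformed)

    roster = pd.concat(
        [roster_base.assign(method=m) for m in (DEEP_METHOD, ATLAS_METHOD)],
        ignore_index=True,
    )

    # ---- reliability evaluation ------------------------------------------
    say("evaluating reliability pairs")
    pairs = build_pairs(roster, "head_motion")
    region_metrics = evaluate_pairs(pairs, masks)
    summary = aggregate(region_metrics)

    results = []
    for metric in METRICS:
        for macro in sorted(summary["macro_region"].unique()):
            for ptype in sorted(summary["pairing_type"].unique()):
                try:
                    results.append(
                        compare_methods(
                            summary, DEEP_METHOD, ATLAS_METHOD, metric, macro, ptype
                        )
                    )
                except ValueError:
                    continue  # too few observations in this cell
    bh_adjust(results)
    stats_df = stat_results_frame(results)

    # ---- artifacts --------------------------------------------------------
    say("writing artifacts")
    roster.to_csv(out / "roster.csv", index=False)
    region_metrics.to_csv(out / "region_metrics.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    stats_df.to_csv(out / "stats.csv", index=False)
    pd.DataFrame(crop_log).to_csv(out / "crop_training_log.csv", index=False)
    pd.DataFrame(seg_log).to_csv(out / "seg_training_log.csv", index=False)
    (out / "recovery.json").write_text(json.dumps(recovery, indent=2))
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["geometry"] = dataclasses.asdict(cfg.geometry)
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2))
    crop_model.save(out / "crop_model")
    seg_model.save(out / "seg_model")

    return DemoResult(
        out_dir=out, config=cfg, roster=roster, region_metrics=region_metrics,
        summary=summary, stats=stats_df, recovery=recovery,
        crop_model=crop_model, seg_model=seg_model,
    )
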