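"""End-to-end pipeline: simulate -> segment -> label -> dataset -> train ->
predict -> recapitulate -> evaluate.

A :class:`~spherotype.config.PipelineConfig` plus its seed fully determines
the run; the config is echoed into the output directory next to a
``metrics.json`` manifest, so identical configs reproduce identical metrics.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, save_config
from .dataset import (
    augment_rotations,
    curate_and_balance,
    extract_and_standardize,
    hold_out_strict,
    samples_from_rois,
)
from .evaluation import CountPair, accuracy_summary, count_agreement
from .grids import VoxelGrid, write_labels
from .ground_truth import (
    AMBIGUOUS,
    assign_ground_truth,
    segment_reference_cells,
    threshold_reference,
)
from .recap import recapitulate, to_rgb
from .segmentation import (
    deduplicate_rois,
    make_mask,
    postfilter_cells,
    prepare_watershed_inputs,
    watershed_from_markers,
)
from .synthetic import multi_image_rosters
from .tiling import tile_stack

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def process_image(name: str, grid: VoxelGrid, cfg: PipelineConfig) -> dict:
    """Segment one image and assign reference-channel ground truth.

    Returns ROIs (global offsets), assignments, labeled samples, and counts.
    Images wider than one tile are tiled with overlap and deduplicated.
    """
    nz, ny, nx = grid.shape
    tile_px = min(cfg.tile_px, ny, nx)
    tiles = tile_stack(grid, tile_px=tile_px, overlap_frac=cfg.overlap_frac)
    per_tile_rois, tile_dims, samples = [], [], []
    assignments_all = []
    for tile in tiles:
        inputs = prepare_watershed_inputs(tile, cfg.segmentation)
        mask = make_mask(tile, cfg.segmentation)
        labels = watershed_from_markers(
            inputs["flooding"], inputs["seeds"], mask, cfg.segmentation.connectivity
        )
        _, rois = postfilter_cells(labels, tile.grid, cfg.segmentation)
        masks = threshold_reference(tile)
        ref = segment_reference_cells(tile, inputs["seeds"], masks)
        assignments = assign_ground_truth(rois, masks, ref)
        labels_map = {a.label_id: a.label for a in assignments}
        f_map = {a.label_id: a.f_index for a in assignments}
        samples.extend(
            samples_from_rois(
                tile.grid, rois, labels_map, name, f_indices=f_map,
                pad_center=cfg.dataset.pad_center,
            )
        )
        per_tile_rois.append(rois)
        tile_dims.append(tile.grid.shape)
        assignments_all.extend(assignments)
    rois = deduplicate_rois(per_tile_rois, tile_dims) if len(tiles) > 1 else per_tile_rois[0]
    n_ambiguous = sum(1 for a in assignments_all if a.label == AMBIGUOUS)
    return {
        "name": name,
        "rois": rois,
        "assignments": assignments_all,
        "samples": samples,
        "auto_count": len(rois),
        "n_ambiguous": n_ambiguous,
    }


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes ``config.yaml``, ``metrics.json``, ``runs.csv`` and the
    recapitulated class/RGB TIFFs of the first image.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "config.yaml")
    metrics: dict = {"seed": cfg.seed, "images": {}}
    t0 = time.time()

    def stage(fn, name, *args, **kwargs):
        try:
            t = time.time()
            result = fn(*args, **kwargs)
            logger.info("stage %s done in %.1f s", name, time.time() - t)
            return result
        except Exception as exc:
            raise StageError(f"stage {name}: {exc}") from exc

    images = stage(
        multi_image_rosters, "simulate", cfg.n_images, cfg.simulation, cfg.seed,
        n_cells_spread=max(cfg.simulation.n_cells // 3, 1),
    )

    per_image = []
    all_samples = []
    count_pairs = []
    for name, grid, roster in images:
        info = stage(process_image, f"segment[{name}]", name, grid, cfg)
        info["roster_count"] = len(roster)
        info["grid"] = grid
        info["roster"] = roster
        per_image.append(info)
        all_samples.extend(info["samples"])
        count_pairs.append(CountPair(name, len(roster), info["auto_count"]))
        metrics["images"][name] = {
            "roster_count": len(roster),
            "auto_count": info["auto_count"],
            "labeled_cells": len(info["samples"]),
            "ambiguous": info["n_ambiguous"],
        }

    metrics["counting"] = {
        k: v for k, v in stage(count_agreement, "evaluate-counts", count_pairs).items()
        if k in ("ratio", "r_squared", "per_image_ratio")
    }

    working, strict = stage(
        hold_out_strict, "hold-out", all_samples, cfg.dataset.holdout_images, cfg.seed
    )
    balanced = stage(curate_and_balance, "balance", working, cfg.seed)
    if cfg.dataset.augment:
        balanced = augment_rotations(balanced)
        strict = augment_rotations(strict)
    metrics["dataset"] = {
        "labeled_cells": len(all_samples),
        "working": len(working),
        "strict_test": len(strict),
        "after_balancing_and_augmentation": len(balanced),
    }

    from .nn.train import train_bootstrap

    model, results = stage(
        train_bootstrap, "train", balanced, cfg.model,
        strict=strict or None, proportions=cfg.dataset.proportions,
        group_rotations=cfg.dataset.group_rotations,
    )
    pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "best_epoch": r.best_epoch,
                "best_val_loss": r.best_val_loss,
                "test_accuracy": r.test_accuracy,
                "strict_accuracy": r.strict_accuracy,
            }
            for r in results
        ]
    ).to_csv(out_dir / "runs.csv", index=False)
    summary = stage(
        accuracy_summary, "evaluate-accuracy", results,
        seed=cfg.seed, which="strict" if strict else "test",
    )
    best = min(results, key=lambda r: r.best_val_loss)
    metrics["classifier"] = {
        "median_accuracy": summary["median"],
        "max_accuracy": summary["max"],
        "ci95": [summary["ci95_low"], summary["ci95_high"]],
        "best_run": best.run_id,
        "best_val_loss": best.best_val_loss,
        "median_best_epoch": float(np.median([r.best_epoch for r in results])),
    }

    # recapitulate the first image with the trained classifier
    first = per_image[0]
    preds = {}
    for roi in first["rois"]:
        tensor = extract_and_standardize(first["grid"], roi, pad_center=cfg.dataset.pad_center)
        if tensor is None:
            continue
        probs = model.predict_proba(tensor[None])
        from .dataset import LABELS

        preds[roi.label_id] = LABELS[int(probs[0].argmax())]
    recap_rois = [r for r in first["rois"] if r.label_id in preds]
    recap = stage(recapitulate, "recapitulate", recap_rois, preds, first["grid"].shape)
    from .grids import LabelVolume

    write_labels(
        LabelVolume(labels=recap.class_labels.astype(np.int64),
                    voxel_size=first["grid"].voxel_size),
        out_dir / "recap_class.tiff",
    )
    import tifffile

    tifffile.imwrite(out_dir / "recap_rgb.tiff", to_rgb(recap))
    metrics["recap"] = {
        "image": first["name"],
        "n_cells": len(recap_rois),
        "overlap_voxels": recap.overlap_voxels,
    }
    logger.info("pipeline finished in %.1f s", time.time() - t0)

    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return out_dir
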