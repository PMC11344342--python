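"""Shared fixtures.

Heavy artifacts (synthetic corpora, trained classifiers, pipeline runs) are
session-scoped and shared between the unit suite and the acceptance suite so
each is computed exactly once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from spherotype.dataset import curate_and_balance, hold_out_strict, samples_from_roster
from spherotype.ground_truth import (
    assign_ground_truth,
    segment_reference_cells,
    threshold_reference,
)
from spherotype.nn.model import ModelConfig
from spherotype.nn.train import train_bootstrap
from spherotype.segmentation import (
    SegmentationParams,
    make_mask,
    postfilter_cells,
    prepare_watershed_inputs,
    watershed_from_markers,
)
from spherotype.synthetic import (
    SpheroidSpec,
    generate_spheroid,
    multi_image_rosters,
    roster_to_reference_labels,
)
from spherotype.tiling import tile_stack


@pytest.fixture(scope="session")
def spheroid30():
    """One 30-cell spheroid image with roster and body-label oracle."""
    spec = SpheroidSpec(n_cells=30, seed=1)
    grid, roster = generate_spheroid(spec)
    ref = roster_to_reference_labels(roster, grid.shape, grid.voxel_size)
    return {"spec": spec, "grid": grid, "roster": roster, "ref": ref}


@pytest.fixture(scope="session")
def spheroid30_clean():
    """Noise-free twin of spheroid30 for exactness-sensitive checks."""
    spec = SpheroidSpec(n_cells=30, seed=1, noise_sd=0.0)
    grid, roster = generate_spheroid(spec)
    ref = roster_to_reference_labels(roster, grid.shape, grid.voxel_size)
    return {"spec": spec, "grid": grid, "roster": roster, "ref": ref}


def _segment_and_label(bundle):
    grid = bundle["grid"]
    params = SegmentationParams()
    tile = tile_stack(grid, tile_px=max(grid.shape[1:]))[0]
    inputs = prepare_watershed_inputs(tile, params)
    mask = make_mask(tile, params)
    labels = watershed_from_markers(
        inputs["flooding"], inputs["seeds"], mask, params.connectivity
    )
    relabeled, rois = postfilter_cells(labels, tile.grid, params)
    masks = threshold_reference(tile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refcells = segment_reference_cells(tile, inputs["seeds"], masks)
    assignments = assign_ground_truth(rois, masks, refcells)
    return {
        "tile": tile,
        "params": params,
        "inputs": inputs,
        "mask": mask,
        "labels": relabeled,
        "rois": rois,
        "masks": masks,
        "refcells": refcells,
        "assignments": assignments,
    }


@pytest.fixture(scope="session")
def segmented30(spheroid30):
    """Full segmentation + ground-truth products for the noisy spheroid."""
    return _segment_and_label(spheroid30)


@pytest.fixture(scope="session")
def segmented30_clean(spheroid30_clean):
    return _segment_and_label(spheroid30_clean)


# ---------------------------------------------------------------------------
# classifier fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def signal_corpus():
    """408 oracle-labeled cells from 8 images at full texture separation."""
    spec = SpheroidSpec(n_cells=51, texture_effect=1.0)
    images = multi_image_rosters(8, spec, seed=101)
    samples = samples_from_roster(images)
    working, strict = hold_out_strict(samples, 1, seed=7)
    working = curate_and_balance(working, seed=7)
    return {"working": working, "strict": strict, "images": images}


@pytest.fixture(scope="session")
def signal_training(signal_corpus):
    """Bootstrapped training (3 runs x 10 epochs) on the signal corpus."""
    config = ModelConfig(seed=13)
    model, results = train_bootstrap(
        signal_corpus["working"], config, strict=signal_corpus["strict"],
        proportions=(0.6, 0.2, 0.2), n_runs=3, epochs=10,
    )
    return {"model": model, "results": results, "config": config}


def _small_run(effect: float, seed_images: int, seed_train: int):
    spec = SpheroidSpec(n_cells=24, texture_effect=effect)
    images = multi_image_rosters(5, spec, seed=seed_images)
    samples = samples_from_roster(images)
    working, strict = hold_out_strict(samples, 1, seed=3)
    working = curate_and_balance(working, seed=3)
    config = ModelConfig(seed=seed_train)
    model, results = train_bootstrap(working, config, strict=strict, n_runs=1, epochs=6)
    return {"model": model, "result": results[0], "working": working, "strict": strict}


@pytest.fixture(scope="session")
def small_run_t0():
    return _small_run(0.0, seed_images=11, seed_train=5)


@pytest.fixture(scope="session")
def small_run_t05():
    return _small_run(0.5, seed_images=11, seed_train=5)


@pytest.fixture(scope="session")
def small_run_t10():
    return _small_run(1.0, seed_images=11, seed_train=5)


@pytest.fixture(scope="session")
def augmented_training():
    """A run trained WITH rotation augmentation (invariance properties)."""
    from spherotype.dataset import augment_rotations

    spec = SpheroidSpec(n_cells=16, texture_effect=1.0)
    images = multi_image_rosters(6, spec, seed=11)
    # centered padding keeps content position rotation-symmetric
    samples = samples_from_roster(images, pad_center=True)
    working, strict = hold_out_strict(samples, 2, seed=3)
    working = augment_rotations(curate_and_balance(working, seed=3))
    config = ModelConfig(seed=5)
    model, results = train_bootstrap(working, config, strict=strict,
                                     n_runs=1, epochs=8)
    return {"model": model, "result": results[0], "strict": strict}


@pytest.fixture(scope="session")
def ablation_corpus():
    """Corpus in which only reflectance carries class information."""
    spec = SpheroidSpec(n_cells=24, texture_effect=1.0, transmission_effect=0.0)
    images = multi_image_rosters(5, spec, seed=23)
    samples = samples_from_roster(images)
    working, strict = hold_out_strict(samples, 1, seed=3)
    working = curate_and_balance(working, seed=3)
    return {"working": working, "strict": strict}


@pytest.fixture(scope="session")
def demo_metrics(tmp_path_factory):
    """The demo pipeline executed twice with one config (determinism probe)."""
    import json

    from spherotype.config import config_from_dict
    from spherotype.pipeline import run_pipeline

    cfg_dict = {
        "seed": 42,
        "n_images": 3,
        "simulation": {"n_cells": 12, "spheroid_radius_um": 40.0},
        "model": {"n_runs": 2, "max_epochs": 5, "seed": 42},
    }
    out = []
    for tag in ("a", "b"):
        cfg = config_from_dict(dict(cfg_dict))
        d = tmp_path_factory.mktemp(f"demo_{tag}")
        run_pipeline(cfg, d)
        with open(d / "metrics.json") as fh:
            out.append(json.load(fh))
    return out
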