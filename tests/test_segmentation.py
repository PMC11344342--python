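"""Watershed segmentation: seeds, masks, flooding, filters, orchestration."""

import warnings

import numpy as np
import pytest

from helpers import flood_oracle, random_flood_instance
from spherotype.grids import LabelVolume, VoxelGrid
from spherotype.segmentation import (
    SegmentationParams,
    make_mask,
    morphological_gradient,
    postfilter_cells,
    prepare_watershed_inputs,
    segment_cells,
    train_mask_classifier,
    watershed_from_markers,
)
from spherotype.synthetic import (
    SpheroidSpec,
    generate_spheroid,
    match_rois_to_roster,
    roster_to_reference_labels,
)
from spherotype.tiling import tile_stack


class TestParams:
    def test_volume_bounds_validated(self):
        with pytest.raises(ValueError):
            SegmentationParams(vmin_vox=100, vmax_vox=50)

    def test_unknown_mask_method_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(mask_method="weka")


class TestPrepareInputs:
    def test_two_nuclei_twelve_um_apart_two_seeds(self):
        """Brute-force check: the generated dapi volume has exactly two
        maxima at this spacing, and seed detection finds both."""
        vs = (4.0, 0.8, 0.8)
        dapi = np.zeros((10, 40, 40))
        zz, yy, xx = np.mgrid[0:10, 0:40, 0:40].astype(float)
        for cy in (14.0, 29.0):  # 15 px = 12 um apart in y
            d2 = ((zz - 5) * 4) ** 2 + ((yy - cy) * 0.8) ** 2 + ((xx - 20) * 0.8) ** 2
            dapi += 1000 * np.exp(-d2 / (2 * 3.0**2))
        grid = VoxelGrid(
            channels={"dapi": dapi, "reflectance": np.ones_like(dapi)}, voxel_size=vs
        )
        tile = tile_stack(grid, tile_px=40)[0]
        params = SegmentationParams(seed_min_distance_um=6.0)
        out = prepare_watershed_inputs(tile, params)
        assert out["seeds"].ids().size == 2

    def test_uniform_dapi_yields_no_seeds_no_cells(self):
        grid = VoxelGrid(
            channels={"dapi": np.full((6, 30, 30), 100.0),
                      "reflectance": np.full((6, 30, 30), 100.0)}
        )
        tile = tile_stack(grid, tile_px=30)[0]
        out = prepare_watershed_inputs(tile, SegmentationParams())
        assert out["seeds"].ids().size == 0
        labels = watershed_from_markers(
            out["flooding"], out["seeds"], np.ones((6, 30, 30), bool)
        )
        assert labels.labels.sum() == 0

    def test_gradient_of_constant_is_zero(self):
        assert morphological_gradient(np.full((4, 5, 5), 3.0)).max() == 0.0

    def test_missing_channel_rejected(self):
        grid = VoxelGrid(channels={"dapi": np.zeros((2, 4, 4))})
        with pytest.raises(ValueError, match="reflectance"):
            prepare_watershed_inputs(tile_stack(grid, tile_px=4)[0], SegmentationParams())


class TestWatershedOracle:
    def test_matches_bruteforce_flood_on_random_instances(self):
        """Quick screen (the full 100-instance sweep runs in the acceptance
        suite); ties are abundant because altitudes are small integers."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            flood, seeds, mask = random_flood_instance(rng, max_dim=12)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ours = watershed_from_markers(flood, LabelVolume(seeds), mask)
            expected = flood_oracle(flood, seeds, mask)
            np.testing.assert_array_equal(ours.labels, expected)

    def test_single_seed_fills_connected_mask(self):
        mask = np.zeros((3, 6, 6), bool)
        mask[1, 1:5, 1:5] = True
        seeds = np.zeros((3, 6, 6), np.int64)
        seeds[1, 2, 2] = 1
        labels = watershed_from_markers(np.zeros((3, 6, 6)), LabelVolume(seeds), mask)
        np.testing.assert_array_equal(labels.labels > 0, mask)

    def test_flat_flooding_symmetric_mask_equal_split(self):
        # even-width corridor: no equidistant midline voxel, so the
        # label-order tie-break still yields a symmetric split
        mask = np.zeros((1, 4, 10), bool)
        mask[0, 1:3, 1:9] = True
        seeds = np.zeros((1, 4, 10), np.int64)
        seeds[0, 1, 2] = 1
        seeds[0, 1, 7] = 2
        labels = watershed_from_markers(np.zeros(mask.shape), LabelVolume(seeds), mask)
        n1 = (labels.labels == 1).sum()
        n2 = (labels.labels == 2).sum()
        assert n1 + n2 == mask.sum()
        assert n1 == n2

    def test_seeds_outside_mask_dropped_with_warning(self):
        mask = np.zeros((1, 5, 5), bool)
        mask[0, :2] = True
        seeds = np.zeros((1, 5, 5), np.int64)
        seeds[0, 0, 0] = 1
        seeds[0, 4, 4] = 2
        with pytest.warns(UserWarning, match="dropped"):
            labels = watershed_from_markers(np.zeros(mask.shape), LabelVolume(seeds), mask)
        assert set(np.unique(labels.labels)) == {0, 1}

    def test_mask_shrink_never_grows_regions(self):
        rng = np.random.default_rng(7)
        flood, seeds, mask = random_flood_instance(rng, max_dim=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = watershed_from_markers(flood, LabelVolume(seeds), mask)
            smaller = mask.copy()
            drop = np.argwhere(mask)
            for idx in drop[:: max(len(drop) // 10, 1)]:
                smaller[tuple(idx)] = False
            shrunk = watershed_from_markers(flood, LabelVolume(seeds), smaller)
        for sid in np.unique(seeds[seeds > 0]):
            assert (shrunk.labels == sid).sum() <= (full.labels == sid).sum()


class TestMask:
    def test_threshold_mask_covers_cell_bodies(self, spheroid30_clean):
        grid = spheroid30_clean["grid"]
        ref = spheroid30_clean["ref"]
        tile = tile_stack(grid, tile_px=max(grid.shape[1:]))[0]
        mask = make_mask(tile, SegmentationParams())
        body = ref.labels > 0
        assert (mask & body).sum() / body.sum() >= 0.99

    def test_all_zero_channels_empty_mask(self):
        grid = VoxelGrid(
            channels={"dapi": np.zeros((3, 8, 8)), "reflectance": np.zeros((3, 8, 8))}
        )
        tile = tile_stack(grid, tile_px=8)[0]
        assert make_mask(tile, SegmentationParams()).sum() == 0

    def test_classifier_mode_requires_model(self):
        grid = VoxelGrid(
            channels={"dapi": np.zeros((3, 8, 8)), "reflectance": np.zeros((3, 8, 8))}
        )
        tile = tile_stack(grid, tile_px=8)[0]
        with pytest.raises(ValueError, match="classifier"):
            make_mask(tile, SegmentationParams(mask_method="pixel_classifier"))

    def test_pixel_classifier_from_scribbles_generalizes(self):
        """200 scribble voxels per class on one image; voxel accuracy > 0.9
        on a held-out image, judged against the generator's body oracle."""
        rng = np.random.default_rng(11)
        masks = {}
        for i, seed in enumerate((31, 32)):
            spec = SpheroidSpec(n_cells=15, seed=seed)
            grid, roster = generate_spheroid(spec)
            body = roster_to_reference_labels(roster, grid.shape, grid.voxel_size).labels > 0
            masks[i] = (grid, body)
        train_grid, train_body = masks[0]
        scrib = np.zeros(train_grid.shape, dtype=np.int8)
        cell_idx = np.argwhere(train_body)
        interior = ~train_body
        interior[0] = interior[-1] = False  # keep scribbles off interface planes
        matrix_idx = np.argwhere(interior)
        for idx in cell_idx[rng.choice(len(cell_idx), 200, replace=False)]:
            scrib[tuple(idx)] = 1
        for idx in matrix_idx[rng.choice(len(matrix_idx), 200, replace=False)]:
            scrib[tuple(idx)] = 2
        clf = train_mask_classifier(train_grid, scrib, seed=0)
        test_grid, test_body = masks[1]
        tile = tile_stack(test_grid, tile_px=max(test_grid.shape[1:]))[0]
        pred = make_mask(tile, SegmentationParams(mask_method="pixel_classifier"), clf)
        inner = slice(1, -1)  # interface planes are neither class
        acc = (pred[inner] == test_body[inner]).mean()
        assert acc > 0.9


class TestPostfilter:
    def _mk(self, lab):
        vol = LabelVolume(lab)
        rng = np.random.default_rng(0)
        dapi = rng.integers(50, 60, lab.shape).astype(float)
        dapi[lab > 0] = 5000.0  # nuclei clearly above background
        grid = VoxelGrid(channels={"dapi": dapi})
        return vol, grid

    def test_volume_bounds_inclusive_at_15(self):
        lab = np.zeros((8, 12, 12), dtype=np.int64)
        lab[2, 2:4, 2:9] = 1          # 14 voxels -> removed
        lab[5, 5:8, 5:10] = 2         # 15 voxels -> kept
        vol, grid = self._mk(lab)
        _, rois = postfilter_cells(vol, grid, SegmentationParams())
        assert [r.volume_vox for r in rois] == [15]

    def test_border_touching_removed(self):
        lab = np.zeros((8, 12, 12), dtype=np.int64)
        lab[3, 0, 3:9] = 1            # touches y border
        lab[0, 5:7, 5:9] = 2          # touches top z plane
        lab[4, 4:8, 4:8] = 3          # interior
        vol, grid = self._mk(lab)
        _, rois = postfilter_cells(vol, grid, SegmentationParams())
        assert len(rois) == 1 and rois[0].volume_vox == 16

    def test_dim_nuclei_removed_by_background_rule(self):
        lab = np.zeros((8, 12, 12), dtype=np.int64)
        lab[3, 3:7, 3:7] = 1
        lab[5, 5:9, 5:9] = 2
        vol = LabelVolume(lab)
        dapi = np.full(lab.shape, 100.0)
        dapi[lab == 2] = 500.0        # only region 2 exceeds background
        grid = VoxelGrid(channels={"dapi": dapi})
        _, rois = postfilter_cells(vol, grid, SegmentationParams())
        assert len(rois) == 1
        assert rois[0].measurements["dapi"]["mean"] == 500.0


class TestSegmentCells:
    def test_recovers_separated_cells_with_full_precision(self, spheroid30, segmented30):
        rois = segmented30["rois"]
        roster = spheroid30["roster"]
        matches = match_rois_to_roster(rois, spheroid30["ref"])
        assert len(rois) / len(roster) >= 0.8
        assert all(m is not None for m in matches.values())

    def test_each_roi_contains_exactly_one_seed_and_disjoint(self, segmented30):
        seeds = segmented30["inputs"]["seeds"].labels
        lab = segmented30["labels"].labels
        seen = set()
        for roi in segmented30["rois"]:
            vz, vy, vx = roi.voxels.T
            ids = np.unique(seeds[vz, vy, vx])
            ids = ids[ids > 0]
            assert ids.size == 1
            assert ids[0] not in seen
            seen.add(ids[0])
            assert (np.unique(lab[vz, vy, vx]) == roi.label_id).all()

    def test_empty_tile_no_cells(self):
        grid = VoxelGrid(
            channels={"dapi": np.full((6, 40, 40), 50.0),
                      "reflectance": np.full((6, 40, 40), 50.0)}
        )
        tile = tile_stack(grid, tile_px=40)[0]
        assert segment_cells(tile, SegmentationParams()) == []

    def test_determinism(self, spheroid30):
        grid = spheroid30["grid"]
        tile = tile_stack(grid, tile_px=max(grid.shape[1:]))[0]
        a = segment_cells(tile, SegmentationParams())
        b = segment_cells(tile, SegmentationParams())
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.label_id == rb.label_id
            np.testing.assert_array_equal(ra.voxels, rb.voxels)
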