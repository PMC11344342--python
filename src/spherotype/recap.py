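"""Recapitulation: repaint classified cells into the original 3D volume.

Each classified ROI is painted at its global coordinates with an integer
class code (1 = fibroblast, 2 = tumor), reconstructing a pseudo-stained
volume from label-free classifications.  An 8-bit RGB preview (green =
fibroblast, red = tumor) is derivable for figures; the integer volume is the
analysis product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import RoiRecord
from .synthetic import FIBROBLAST, TUMOR

logger = logging.getLogger(__name__)

CLASS_CODES = {FIBROBLAST: 1, TUMOR: 2}


@dataclass
class RecapVolume:
    class_labels: np.ndarray                  # 0 background, 1 fib, 2 tumor
    provenance: dict[int, int] = field(default_factory=dict)  # roi label -> code
    overlap_voxels: int = 0                   # voxels claimed by >1 ROI


def recapitulate(
    rois: list[RoiRecord],
    predictions: dict[int, str],
    original_dims: tuple[int, int, int],
) -> RecapVolume:
    """Paint each ROI's voxels with its predicted class at global coordinates.

    Overlapping ROIs are resolved deterministically: the lower label_id wins
    (ROIs are processed in label order and later claims on painted voxels
    are dropped and counted).
    """
    vol = np.zeros(original_dims, dtype=np.uint8)
    provenance = {}
    overlap = 0
    for roi in sorted(rois, key=lambda r: r.label_id):
        if roi.label_id not in predictions:
            raise ValueError(f"no prediction for ROI {roi.label_id}")
        code = CLASS_CODES[predictions[roi.label_id]]
        gvox = roi.global_voxels()
        if gvox.min() < 0 or (gvox >= np.array(original_dims)).any():
            raise ValueError(f"ROI {roi.label_id} extends outside {original_dims}")
        vz, vy, vx = gvox.T
        free = vol[vz, vy, vx] == 0
        n_clash = int((~free).sum())
        if n_clash:
            overlap += n_clash
            logger.info("ROI %d: %d overlapping voxels kept by earlier ROI",
                        roi.label_id, n_clash)
        vol[vz[free], vy[free], vx[free]] = code
        provenance[roi.label_id] = code
    return RecapVolume(class_labels=vol, provenance=provenance, overlap_voxels=overlap)


def to_rgb(recap: RecapVolume) -> np.ndarray:
    """8-bit (z, y, x, 3) preview: green = fibroblast, red = tumor."""
    vol = recap.class_labels
    rgb = np.zeros(vol.shape + (3,), dtype=np.uint8)
    rgb[..., 1] = np.where(vol == CLASS_CODES[FIBROBLAST], 255, 0)
    rgb[..., 0] = np.where(vol == CLASS_CODES[TUMOR], 255, 0)
    return rgb
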