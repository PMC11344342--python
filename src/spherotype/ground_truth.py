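"""Ground-truth labels for segmented ROIs from the reference channels.

At training time the green (fibroblast) and red (tumor) reference stains are
available.  Each channel is binarized by an automatic global threshold —
Huang's fuzzy-entropy criterion for green, Li's cross-entropy criterion for
red — and reference cells are segmented by the same marker-controlled
watershed used for the label-free channels (flood = gradient of the
reference channel, mask = its threshold).  A segmented ROI is then labeled
by its F index, F/(F+C), the fibroblast fraction of reference-stain voxels
inside the ROI: > 0.5 means fibroblast, <= 0.5 means tumor cell.  The label
is accepted only when the ROI overlaps a stain by at least 50%, overlaps its
most similar reference cell by more than 90%, and the F-index class agrees
with that reference cell's class; otherwise the ROI is ambiguous (these are
the discordant cells excluded from training).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import LabelVolume, RoiRecord
from .segmentation import _normalize, morphological_gradient, watershed_from_markers
from .synthetic import FIBROBLAST, TUMOR
from .tiling import Tile

AMBIGUOUS = "ambiguous"

STAIN_OVERLAP_MIN = 0.5      # inclusive ("minimum 50% overlap")
REFCELL_OVERLAP_MIN = 0.9    # strict ("overlap of over 90%")


@dataclass
class GroundTruthAssignment:
    label_id: int
    f_area: int
    c_area: int
    f_index: float                 # nan when F + C == 0
    stain_overlap_frac: float
    best_gt_overlap_frac: float
    label: str                     # fibroblast | tumor | ambiguous


def threshold_huang(image: np.ndarray, nbins: int = 256) -> float:
    """Huang & Wang fuzzy-entropy automatic threshold.

    Minimizes Shannon fuzziness of the two-class membership over all
    candidate thresholds of a ``nbins``-level histogram; returns the
    threshold in image intensity units (binarize with ``image > t``).
    """
    img = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise ValueError("constant image has no threshold")
    hist, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(np.float64)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * centers)
    total_w, total_wx = cw[-1], cwx[-1]

    # class means for every candidate threshold t (= last bin of class 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(cw > 0, cwx / cw, 0.0)
        mu1 = np.where(
            (total_w - cw) > 0, (total_wx - cwx) / (total_w - cw), 0.0
        )
    C = hi - lo
    g = centers[None, :]                      # gray level axis
    m0 = mu0[:, None]
    m1 = mu1[:, None]
    t_idx = np.arange(nbins)
    in0 = g <= centers[t_idx][:, None]        # membership of bin to class 0
    mu_of_g = np.where(in0, m0, m1)
    u = 1.0 / (1.0 + np.abs(g - mu_of_g) / C)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    S = -u * np.log(u) - (1 - u) * np.log(1 - u)
    fuzziness = (S * w[None, :]).sum(axis=1)
    # valid thresholds: both classes non-empty
    valid = (cw > 0) & (cw < total_w)
    if not valid.any():
        raise ValueError("degenerate histogram")
    fuzziness[~valid] = np.inf
    best = int(np.argmin(fuzziness))
    return float(edges[best + 1])


def threshold_reference(tile: Tile) -> dict[str, np.ndarray]:
    """Binarize the reference stains: Huang for green, Li for red."""
    from skimage.filters import threshold_li

    grid = tile.grid if isinstance(tile, Tile) else tile
    for ch in ("green", "red"):
        if ch not in grid.channels:
            raise ValueError(f"tile is missing reference channel {ch!r}")
    out = {}
    green = np.asarray(grid.channels["green"], dtype=np.float64)
    red = np.asarray(grid.channels["red"], dtype=np.float64)
    if green.max() <= green.min():
        warnings.warn("green channel is constant; empty fibroblast mask", stacklevel=2)
        out["green_mask"] = np.zeros(grid.shape, dtype=bool)
    else:
        out["green_mask"] = green > threshold_huang(green)
    if red.max() <= red.min():
        warnings.warn("red channel is constant; empty tumor mask", stacklevel=2)
        out["red_mask"] = np.zeros(grid.shape, dtype=bool)
    else:
        out["red_mask"] = red > threshold_li(red)
    return out


def segment_reference_cells(
    tile: Tile,
    seeds: LabelVolume,
    masks: dict[str, np.ndarray],
    connectivity: int = 26,
) -> dict[str, LabelVolume]:
    """Marker-controlled watershed per reference channel.

    The dapi seed markers are reused; each channel floods on its own
    morphological gradient inside its own threshold mask, yielding the
    reference ("ground truth") cell label volumes.
    """
    grid = tile.grid if isinstance(tile, Tile) else tile
    out = {}
    for ch, mask_key, out_key in (
        ("green", "green_mask", "green_labels"),
        ("red", "red_mask", "red_labels"),
    ):
        flood = morphological_gradient(_normalize(grid.channels[ch]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # seeds of the other class sit outside
            out[out_key] = watershed_from_markers(
                flood, seeds, masks[mask_key], connectivity
            )
    return out


def compute_f_index(f_area: int, c_area: int) -> tuple[float, str]:
    """F index F/(F+C) and the class it implies (boundary 0.5 -> tumor)."""
    if f_area < 0 or c_area < 0:
        raise ValueError("areas must be non-negative")
    total = f_area + c_area
    if total == 0:
        raise ValueError("F + C = 0: F index undefined; mark ROI ambiguous")
    f_index = f_area / total
    return f_index, (FIBROBLAST if f_index > 0.5 else TUMOR)


def assign_ground_truth(
    rois: list[RoiRecord],
    masks: dict[str, np.ndarray],
    reference_labels: dict[str, LabelVolume],
    stain_overlap_min: float = STAIN_OVERLAP_MIN,
    refcell_overlap_min: float = REFCELL_OVERLAP_MIN,
) -> list[GroundTruthAssignment]:
    """Label each ROI by F index + overlap criteria; failures are ambiguous."""
    green_mask = np.asarray(masks["green_mask"], dtype=bool)
    red_mask = np.asarray(masks["red_mask"], dtype=bool)
    green_lab = reference_labels["green_labels"].labels
    red_lab = reference_labels["red_labels"].labels

    out = []
    for roi in rois:
        vz, vy, vx = roi.voxels.T
        n = roi.volume_vox
        F = int(green_mask[vz, vy, vx].sum())
        C = int(red_mask[vz, vy, vx].sum())
        stain_overlap = max(F, C) / n

        best_frac = 0.0
        best_class = None
        for lab, cls in ((green_lab, FIBROBLAST), (red_lab, TUMOR)):
            vals = lab[vz, vy, vx]
            vals = vals[vals > 0]
            if vals.size:
                counts = np.bincount(vals)
                top = int(counts.max())
                if top / n > best_frac:
                    best_frac = top / n
                    best_class = cls

        if F + C == 0:
            out.append(
                GroundTruthAssignment(roi.label_id, F, C, math.nan,
                                      stain_overlap, best_frac, AMBIGUOUS)
            )
            continue
        f_index, f_class = compute_f_index(F, C)
        accepted = (
            stain_overlap >= stain_overlap_min
            and best_frac > refcell_overlap_min
            and best_class == f_class
        )
        out.append(
            GroundTruthAssignment(
                roi.label_id, F, C, f_index, stain_overlap, best_frac,
                f_class if accepted else AMBIGUOUS,
            )
        )
    return out


def assignments_to_dataframe(assignments: list[GroundTruthAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label_id": a.label_id,
                "F": a.f_area,
                "C": a.c_area,
                "f_index": a.f_index,
                "stain_overlap_frac": a.stain_overlap_frac,
                "best_gt_overlap_frac": a.best_gt_overlap_frac,
                "label": a.label,
            }
            for a in assignments
        ]
    )
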