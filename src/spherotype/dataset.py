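"""CNN-ready dataset construction: crop, standardize, hold out, curate,
balance, augment, split.

Each segmented cell becomes a 3-channel (dapi, reflectance, transmission)
tensor of exactly 20 x 50 x 50 voxels (z, y, x): the ROI bounding box is
cropped, voxels outside the ROI are zeroed, and the crop is zero-padded to
the standard size; cells exceeding it are rejected as likely segmentation
errors.  Whole source images can be held out as a strict test set, classes
are balanced by down-sampling the majority at its least-confident members,
and each cell is augmented with 90/180/270-degree in-plane rotations.

Samples may be metadata-only (``tensor=None``) so that bookkeeping
operations (balancing, augmentation counts, splits) scale to large corpora
without holding pixel data; tensors are attached or rotated when
materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .grids import RoiRecord, VoxelGrid
from .synthetic import FIBROBLAST, TUMOR

STANDARD_SHAPE = (20, 50, 50)
CHANNEL_ORDER = ("dapi", "reflectance", "transmission")
ROTATIONS = (0, 90, 180, 270)
LABELS = (FIBROBLAST, TUMOR)
SPLITS = ("train", "val", "test", "strict_test")


@dataclass
class CellSample:
    """One standardized cell image with label and provenance."""

    sample_id: str
    label: str
    source_image: str
    roi_label_id: int
    rotation: int = 0
    split: str | None = None
    f_index: float | None = None
    tensor: np.ndarray | None = None   # (3, 20, 50, 50) float32 when present

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.rotation not in ROTATIONS:
            raise ValueError(f"rotation must be one of {ROTATIONS}")
        if self.tensor is not None:
            self.tensor = np.asarray(self.tensor, dtype=np.float32)
            expected = (len(CHANNEL_ORDER),) + STANDARD_SHAPE
            if self.tensor.shape != expected:
                raise ValueError(
                    f"tensor shape {self.tensor.shape} != {expected}"
                )

    @property
    def cell_key(self) -> tuple[str, int]:
        """Provenance key shared by all rotated copies of one cell."""
        return (self.source_image, self.roi_label_id)

    @property
    def confidence(self) -> float:
        """Ground-truth confidence: distance of the F index from 0.5."""
        return abs(self.f_index - 0.5) if self.f_index is not None else float("nan")


@dataclass
class DatasetManifest:
    counts: dict = field(default_factory=dict)  # (label, split, rotation) -> n
    seed: int = 0
    images: dict = field(default_factory=dict)  # split -> sorted source images
    proportions: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def total(self, split: str | None = None) -> int:
        return sum(
            n for (lab, spl, rot), n in self.counts.items()
            if split is None or spl == split
        )


def rotate_tensor(tensor: np.ndarray, rotation: int) -> np.ndarray:
    """In-plane rotation about the z axis (multiples of 90 degrees)."""
    if rotation not in ROTATIONS:
        raise ValueError(f"rotation must be one of {ROTATIONS}")
    k = rotation // 90
    return np.rot90(tensor, k=k, axes=(2, 3)).copy() if k else tensor.copy()


def extract_and_standardize(
    grid: VoxelGrid,
    roi: RoiRecord,
    channels: tuple[str, ...] = CHANNEL_ORDER,
    pad_center: bool = False,
) -> np.ndarray | None:
    """Crop + mask + zero-pad one ROI to the standard tensor, or reject.

    Voxels outside the ROI are zeroed so the tensor encodes the segmented
    cell, not its neighbors.  By default content is anchored at the low
    corner with padding at high indices; ``pad_center`` centers it instead.
    Returns None when any bounding-box dimension exceeds the standard size
    (the rejection is an expected outcome, not an error).
    """
    zmin, zmax, ymin, ymax, xmin, xmax = roi.bbox
    dims = (zmax - zmin + 1, ymax - ymin + 1, xmax - xmin + 1)
    if any(d > s for d, s in zip(dims, STANDARD_SHAPE)):
        return None
    out = np.zeros((len(channels),) + STANDARD_SHAPE, dtype=np.float32)
    local = roi.voxels - np.array([zmin, ymin, xmin])
    if pad_center:
        shift = [(s - d) // 2 for s, d in zip(STANDARD_SHAPE, dims)]
        local = local + np.array(shift)
    lz, ly, lx = local.T
    vz, vy, vx = roi.voxels.T
    for c, ch in enumerate(channels):
        if ch not in grid.channels:
            raise KeyError(f"channel {ch!r} not in grid")
        out[c, lz, ly, lx] = grid.channels[ch][vz, vy, vx]
    return out


def hold_out_strict(
    samples: list[CellSample], images, seed: int = 0
) -> tuple[list[CellSample], list[CellSample]]:
    """Move whole source images to the strict test set (no cell-level leaks).

    ``images`` is a count (>= 1) or a fraction (< 1) of source images.
    """
    all_images = sorted({s.source_image for s in samples})
    n = int(round(images * len(all_images))) if 0 < images < 1 else int(images)
    if n == 0:
        return list(samples), []
    if n > len(all_images):
        raise ValueError(f"requested {n} hold-out images, only {len(all_images)} exist")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(all_images, size=n, replace=False).tolist())
    working, strict = [], []
    for s in samples:
        (strict if s.source_image in chosen else working).append(
            replace(s, split="strict_test") if s.source_image in chosen else s
        )
    return working, strict


def curate_and_balance(samples: list[CellSample], seed: int = 0) -> list[CellSample]:
    """Down-sample the majority class to the minority count.

    The majority's lowest-confidence cells (F index nearest 0.5) are removed
    first; ties are broken by a seeded random permutation.  Ambiguous cells
    must already have been excluded upstream.
    """
    by_label = {lab: [s for s in samples if s.label == lab] for lab in LABELS}
    n_fib, n_tum = len(by_label[FIBROBLAST]), len(by_label[TUMOR])
    if min(n_fib, n_tum) == 0:
        raise ValueError("one class is empty; cannot balance")
    if n_fib == n_tum:
        return list(samples)
    minority, majority = (
        (FIBROBLAST, TUMOR) if n_fib < n_tum else (TUMOR, FIBROBLAST)
    )
    keep_n = len(by_label[minority])
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(by_label[majority]))
    ranked = sorted(
        zip(by_label[majority], tiebreak),
        key=lambda p: (-(p[0].confidence if p[0].f_index is not None else rng.random()), p[1]),
    )
    kept_majority = {id(s) for s, _ in ranked[:keep_n]}
    return [s for s in samples if s.label == minority or id(s) in kept_majority]


def augment_rotations(samples: list[CellSample]) -> list[CellSample]:
    """Expand each sample into its four in-plane rotations (0/90/180/270)."""
    out = []
    for s in samples:
        for rot in ROTATIONS:
            tensor = None
            if s.tensor is not None:
                tensor = rotate_tensor(s.tensor, rot)
            out.append(
                replace(s, rotation=rot, tensor=tensor,
                        sample_id=f"{s.sample_id}_r{rot}")
            )
    return out


def split_train_val_test(
    samples: list[CellSample],
    proportions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    group_rotations: bool = True,
) -> tuple[list[CellSample], DatasetManifest]:
    """Seeded random split into train/val/test.

    With ``group_rotations`` (default) all rotated copies of one cell land in
    the same split, so augmented twins never leak across splits; disable it
    to reproduce augment-then-split behavior.
    """
    if len(proportions) != 3 or abs(sum(proportions) - 1.0) > 1e-9 or min(proportions) < 0:
        raise ValueError("proportions must be 3 non-negative numbers summing to 1")
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")
    if group_rotations:
        grouped: dict[tuple[str, int], list[CellSample]] = {}
        for s in samples:
            grouped.setdefault(s.cell_key, []).append(s)
        units: list[list[CellSample]] = [grouped[k] for k in sorted(grouped)]
    else:
        units = [[s] for s in samples]
    order = rng.permutation(len(units))
    total = len(samples)
    target = [p * total for p in proportions]
    counts = [0, 0, 0]
    out: list[CellSample] = []
    for i in order:
        unit = units[i]
        # assign to the split with the largest remaining deficit
        deficits = [target[j] - counts[j] for j in range(3)]
        j = int(np.argmax(deficits))
        counts[j] += len(unit)
        out.extend(replace(s, split=names[j]) for s in unit)
    manifest = DatasetManifest(seed=seed, proportions=tuple(proportions))
    for s in out:
        key = (s.label, s.split, s.rotation)
        manifest.counts[key] = manifest.counts.get(key, 0) + 1
        manifest.images.setdefault(s.split, set()).add(s.source_image)
    manifest.images = {k: sorted(v) for k, v in manifest.images.items()}
    return out, manifest


def samples_from_rois(
    grid: VoxelGrid,
    rois: list[RoiRecord],
    labels: dict[int, str],
    source_image: str,
    f_indices: dict[int, float] | None = None,
    pad_center: bool = False,
) -> list[CellSample]:
    """Materialize standardized samples for labeled (non-ambiguous) ROIs.

    Oversize ROIs are silently rejected, mirroring the standardization rule.
    """
    out = []
    for roi in rois:
        lab = labels.get(roi.label_id)
        if lab not in LABELS:
            continue
        tensor = extract_and_standardize(grid, roi, pad_center=pad_center)
        if tensor is None:
            continue
        out.append(
            CellSample(
                sample_id=f"{source_image}_roi{roi.label_id}",
                label=lab,
                source_image=source_image,
                roi_label_id=roi.label_id,
                f_index=None if f_indices is None else f_indices.get(roi.label_id),
                tensor=tensor,
            )
        )
    return out


def samples_from_roster(
    images: list[tuple[str, VoxelGrid, list]],
    pad_center: bool = False,
) -> list[CellSample]:
    """Labeled samples via the perfect-segmentation oracle.

    Uses the generator roster's painted cell bodies as ROIs and its true
    class as the label; isolates downstream stages (dataset, classifier)
    from segmentation recall in experiments.
    """
    from .grids import labels_to_rois
    from .synthetic import FIBROBLAST, roster_to_reference_labels

    out = []
    for name, grid, roster in images:
        ref = roster_to_reference_labels(roster, grid.shape, grid.voxel_size)
        rois = labels_to_rois(ref)
        types = {c.cell_id: c.type for c in roster}
        labels = {r.label_id: types[r.label_id] for r in rois}
        f_idx = {
            r.label_id: (1.0 if types[r.label_id] == FIBROBLAST else 0.0)
            for r in rois
        }
        out.extend(
            samples_from_rois(grid, rois, labels, name, f_indices=f_idx,
                              pad_center=pad_center)
        )
    return out


def stack_tensors(samples: list[CellSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (x, y) arrays; y is the label index (0=fib, 1=tum)."""
    missing = [s.sample_id for s in samples if s.tensor is None]
    if missing:
        raise ValueError(f"{len(missing)} samples have no tensor (e.g. {missing[0]})")
    x = np.stack([s.tensor for s in samples]).astype(np.float32)
    y = np.array([LABELS.index(s.label) for s in samples], dtype=np.int64)
    return x, y


def save_dataset(samples: list[CellSample], out_dir) -> None:
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "sample_id": s.sample_id, "label": s.label, "split": s.split or "",
            "rotation": s.rotation, "source_image": s.source_image,
            "roi_id": s.roi_label_id,
            "f_index": np.nan if s.f_index is None else s.f_index,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    tensors = {s.sample_id: s.tensor for s in samples if s.tensor is not None}
    np.savez_compressed(out_dir / "tensors.npz", **tensors)


def load_dataset(in_dir) -> list[CellSample]:
    import pandas as pd

    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "manifest.csv")
    npz = np.load(in_dir / "tensors.npz")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CellSample(
                sample_id=row.sample_id,
                label=row.label,
                source_image=row.source_image,
                roi_label_id=int(row.roi_id),
                rotation=int(row.rotation),
                split=row.split if isinstance(row.split, str) and row.split else None,
                f_index=None if np.isnan(row.f_index) else float(row.f_index),
                tensor=npz[row.sample_id] if row.sample_id in npz else None,
            )
        )
    return out
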