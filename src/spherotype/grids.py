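"""Voxel-grid containers and multichannel TIFF I/O.

The pipeline works on confocal z-stacks stored as multipage TIFF hyperstacks
with pages ordered z-major, channel-minor (plane 0: ch0..chN, plane 1:
ch0..chN, ...).  Coordinates are 0-based ``(z, y, x)`` everywhere; bounding
boxes are inclusive.  Voxel sizes are in micrometres, ``(dz, dy, dx)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Canonical channel set of a full acquisition.
CANONICAL_CHANNELS = ("dapi", "reflectance", "transmission", "green", "red")

#: Default voxel size in micrometres: 4 um z-step, 0.8 um in-plane (1.25 px/um).
DEFAULT_VOXEL_SIZE = (4.0, 0.8, 0.8)


class FormatError(ValueError):
    """Raised for malformed stack files (e.g. page count not divisible)."""


@dataclass
class VoxelGrid:
    """A named-channel 3D intensity volume with anisotropic voxel size.

    Parameters
    ----------
    channels
        Ordered mapping channel-name -> 3D array ``(z, y, x)``.  All channels
        must share one shape; names must be unique (dict enforces this).
    voxel_size
        ``(dz, dy, dx)`` in micrometres, strictly positive.
    origin
        ``(z0, y0, x0)`` voxel offset of this grid within a parent volume;
        ``(0, 0, 0)`` for full images.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelGrid needs at least one channel")
        shapes = {ch: np.asarray(v).shape for ch, v in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channels must be 3D (z,y,x), got shape {first}")
        for ch, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"channel {ch!r} has shape {shp}, expected {first}"
                )
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        self.origin = tuple(int(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def crop(self, zslice: slice, yslice: slice, xslice: slice) -> "VoxelGrid":
        """Axis-aligned crop; the result's origin tracks global coordinates."""
        z0 = self.origin[0] + (zslice.start or 0)
        y0 = self.origin[1] + (yslice.start or 0)
        x0 = self.origin[2] + (xslice.start or 0)
        return VoxelGrid(
            channels={ch: v[zslice, yslice, xslice] for ch, v in self.channels.items()},
            voxel_size=self.voxel_size,
            origin=(z0, y0, x0),
        )


@dataclass
class LabelVolume:
    """Integer instance-label volume; 0 is background."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z,y,x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        self.origin = tuple(int(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class RoiRecord:
    """One segmented cell.

    ``voxels`` is an ``(n, 3)`` integer array of (z,y,x) coordinates local to
    the parent grid; add ``offset`` for global coordinates.  ``bbox`` is the
    inclusive tight bound ``(zmin, zmax, ymin, ymax, xmin, xmax)``.
    """

    label_id: int
    voxels: np.ndarray
    bbox: tuple[int, int, int, int, int, int]
    offset: tuple[int, int, int] = (0, 0, 0)
    volume_vox: int = 0
    volume_um3: float = 0.0
    measurements: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3 or len(self.voxels) == 0:
            raise ValueError("voxels must be a non-empty (n, 3) array")
        if self.label_id <= 0:
            raise ValueError("label_id must be positive")
        if self.volume_vox == 0:
            self.volume_vox = len(self.voxels)
        if self.volume_vox != len(self.voxels):
            raise ValueError("volume_vox inconsistent with voxel set")
        lo = self.voxels.min(axis=0)
        hi = self.voxels.max(axis=0)
        tight = (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
        if tuple(int(b) for b in self.bbox) != tuple(int(b) for b in tight):
            raise ValueError(f"bbox {self.bbox} is not the tight bound {tight}")

    @property
    def centroid(self) -> np.ndarray:
        """Local-coordinate centroid (z, y, x)."""
        return self.voxels.mean(axis=0)

    @property
    def global_centroid(self) -> np.ndarray:
        return self.centroid + np.asarray(self.offset, dtype=float)

    def global_voxels(self) -> np.ndarray:
        return self.voxels + np.asarray(self.offset, dtype=np.int64)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

_META_TAG = "spherotype"


def write_stack(grid: VoxelGrid, path) -> str:
    """Write a VoxelGrid as a multipage TIFF (z-major, channel-minor pages).

    Intensities are stored as 16-bit unsigned (values clipped to [0, 65535]
    and rounded); voxel size and channel names go into the image description
    so the file is self-describing.
    """
    nz, ny, nx = grid.shape
    data = np.empty((nz, len(grid.channels), ny, nx), dtype=np.uint16)
    for c, name in enumerate(grid.channel_names):
        vol = np.asarray(grid.channels[name])
        if np.issubdtype(vol.dtype, np.floating):
            vol = np.clip(np.rint(vol), 0, 65535)
        data[:, c] = vol.astype(np.uint16)
    desc = json.dumps(
        {
            _META_TAG: 1,
            "channels": list(grid.channel_names),
            "voxel_size_um": list(grid.voxel_size),
            "origin": list(grid.origin),
            "page_order": "z-major,channel-minor",
        }
    )
    tifffile.imwrite(
        str(path),
        data.reshape(nz * len(grid.channels), ny, nx),
        description=desc,
        metadata=None,
        photometric="minisblack",
    )
    return str(path)


def read_stack(path, channel_names=None, voxel_size=None) -> VoxelGrid:
    """Read a multipage TIFF into a VoxelGrid.

    Pages must be ordered z-major, channel-minor.  ``channel_names`` and
    ``voxel_size`` override metadata recorded by :func:`write_stack`; for
    foreign files they are required (names) / default to
    :data:`DEFAULT_VOXEL_SIZE`.
    """
    meta = None
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict) and _META_TAG in parsed:
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            meta = None
    if channel_names is None:
        if meta is None:
            raise FormatError(f"{path}: no channel metadata; pass channel_names")
        channel_names = meta["channels"]
    channel_names = list(channel_names)
    if voxel_size is None:
        voxel_size = tuple(meta["voxel_size_um"]) if meta else DEFAULT_VOXEL_SIZE
    origin = tuple(meta["origin"]) if meta else (0, 0, 0)

    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        pages = pages.reshape(-1, *pages.shape[-2:])
    n_pages = pages.shape[0]
    n_ch = len(channel_names)
    if n_ch == 0:
        raise ValueError("channel_names must be non-empty")
    if n_pages % n_ch != 0:
        raise FormatError(
            f"{path}: {n_pages} pages not divisible by {n_ch} channels"
        )
    nz = n_pages // n_ch
    data = pages.reshape(nz, n_ch, *pages.shape[-2:])
    channels = {name: data[:, c].copy() for c, name in enumerate(channel_names)}
    return VoxelGrid(channels=channels, voxel_size=voxel_size, origin=origin)


def write_labels(vol: LabelVolume, path) -> str:
    """Write a label volume as a single-channel uint16/uint32 TIFF."""
    dtype = np.uint16 if (vol.labels.size == 0 or vol.labels.max() < 65536) else np.uint32
    desc = json.dumps(
        {
            _META_TAG: 1,
            "labels": True,
            "voxel_size_um": list(vol.voxel_size),
            "origin": list(vol.origin),
        }
    )
    tifffile.imwrite(str(path), vol.labels.astype(dtype), description=desc,
                     metadata=None, photometric="minisblack")
    return str(path)


def read_labels(path, voxel_size=None) -> LabelVolume:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = None
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict) and _META_TAG in parsed:
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            meta = None
    if data.ndim == 2:
        data = data[None]
    if voxel_size is None:
        voxel_size = tuple(meta["voxel_size_um"]) if meta else DEFAULT_VOXEL_SIZE
    origin = tuple(meta["origin"]) if meta else (0, 0, 0)
    return LabelVolume(labels=data.astype(np.int64), voxel_size=voxel_size, origin=origin)


# ---------------------------------------------------------------------------
# ROI extraction and measurement
# ---------------------------------------------------------------------------

def measure_roi(grid: VoxelGrid, roi: RoiRecord, channel: str) -> dict[str, float]:
    """Integrated/mean/max intensity of one channel over an ROI's voxels."""
    if channel not in grid.channels:
        raise KeyError(f"channel {channel!r} not in grid {grid.channel_names}")
    vol = grid.channels[channel]
    vz, vy, vx = roi.voxels.T
    shape = grid.shape
    if (
        vz.min() < 0 or vy.min() < 0 or vx.min() < 0
        or vz.max() >= shape[0] or vy.max() >= shape[1] or vx.max() >= shape[2]
    ):
        raise ValueError(f"ROI {roi.label_id} has voxels outside grid bounds {shape}")
    vals = vol[vz, vy, vx].astype(np.float64)
    integrated = float(vals.sum())
    return {
        "integrated_intensity": integrated,
        "mean": integrated / roi.volume_vox,
        "max": float(vals.max()),
    }


def labels_to_rois(labels: LabelVolume, grid: VoxelGrid | None = None) -> list[RoiRecord]:
    """Convert a label volume into RoiRecords, measuring every grid channel.

    Records are sorted by ``label_id``.  If ``grid`` is None no measurements
    are taken (geometry only).
    """
    from scipy import ndimage

    if grid is not None and grid.shape != labels.shape:
        raise ValueError(f"labels shape {labels.shape} != grid shape {grid.shape}")
    lab = labels.labels
    dz, dy, dx = labels.voxel_size
    vox_um3 = dz * dy * dx
    rois: list[RoiRecord] = []
    objects = ndimage.find_objects(lab)
    for idx, slc in enumerate(objects):
        if slc is None:
            continue
        label_id = idx + 1
        sub = lab[slc] == label_id
        zz, yy, xx = np.nonzero(sub)
        voxels = np.stack(
            [zz + slc[0].start, yy + slc[1].start, xx + slc[2].start], axis=1
        )
        bbox = (
            int(voxels[:, 0].min()), int(voxels[:, 0].max()),
            int(voxels[:, 1].min()), int(voxels[:, 1].max()),
            int(voxels[:, 2].min()), int(voxels[:, 2].max()),
        )
        roi = RoiRecord(
            label_id=label_id,
            voxels=voxels,
            bbox=bbox,
            offset=labels.origin,
            volume_vox=len(voxels),
            volume_um3=len(voxels) * vox_um3,
        )
        if grid is not None:
            for ch in grid.channel_names:
                roi.measurements[ch] = measure_roi(grid, roi, ch)
        rois.append(roi)
    return rois


def rois_to_dataframe(rois: list[RoiRecord]):
    """Tabulate ROIs (one row each) for CSV export; voxel sets live in the
    companion label TIFF, not the table."""
    import pandas as pd

    rows = []
    for r in rois:
        row = {
            "label_id": r.label_id,
            "volume_vox": r.volume_vox,
            "volume_um3": r.volume_um3,
            "zmin": r.bbox[0], "zmax": r.bbox[1],
            "ymin": r.bbox[2], "ymax": r.bbox[3],
            "xmin": r.bbox[4], "xmax": r.bbox[5],
            "z0": r.offset[0], "y0": r.offset[1], "x0": r.offset[2],
        }
        for ch, stats in r.measurements.items():
            for stat, val in stats.items():
                row[f"{ch}_{stat}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def rois_from_labelvolume(labels: LabelVolume, grid: VoxelGrid | None = None) -> list[RoiRecord]:
    """Alias used by CLI round trips (labels TIFF -> ROI objects)."""
    return labels_to_rois(labels, grid)
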