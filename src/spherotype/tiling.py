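"""Lateral tiling of large z-stacks with overlap and offset tracking.

Large fields of view are split into fixed-size x/y tiles (the z extent is
kept whole) so that segmentation runs on bounded volumes and truncated
border cells can be discarded; the overlap guarantees every interior cell is
fully contained in at least one tile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .grids import VoxelGrid

DEFAULT_TILE_PX = 200
DEFAULT_OVERLAP = 0.2


@dataclass
class Tile:
    grid: VoxelGrid                 # origin holds the tile's global offset
    index: tuple[int, int]          # (row, col) lattice position
    parent_dims: tuple[int, int, int]

    @property
    def origin(self) -> tuple[int, int, int]:
        return self.grid.origin


def _axis_starts(dim: int, tile_px: int, step: int) -> list[int]:
    """Regular lattice starts, with the final tile snapped to the border so
    every tile is exactly ``tile_px`` wide."""
    if tile_px >= dim:
        return [0]
    starts = list(range(0, dim - tile_px + 1, step))
    if starts[-1] + tile_px < dim:
        starts.append(dim - tile_px)
    return starts


def tile_stack(
    grid: VoxelGrid,
    tile_px: int = DEFAULT_TILE_PX,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> list[Tile]:
    """Split a stack into overlapping ``tile_px`` x ``tile_px`` lateral tiles.

    ``step = round(tile_px * (1 - overlap_frac))``; the last tile per axis is
    shifted back to end exactly at the image border.  Tiles larger than the
    image span the whole axis (with a warning).
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    if tile_px < 1:
        raise ValueError("tile_px must be positive")
    nz, ny, nx = grid.shape
    if tile_px > ny or tile_px > nx:
        warnings.warn(
            f"tile_px={tile_px} exceeds image extent {(ny, nx)}; using a single "
            "tile spanning that axis",
            stacklevel=2,
        )
    step = max(int(round(tile_px * (1 - overlap_frac))), 1)
    y_starts = _axis_starts(ny, tile_px, step)
    x_starts = _axis_starts(nx, tile_px, step)
    tiles = []
    for r, ys in enumerate(y_starts):
        for c, xs in enumerate(x_starts):
            sub = grid.crop(
                slice(0, nz),
                slice(ys, min(ys + tile_px, ny)),
                slice(xs, min(xs + tile_px, nx)),
            )
            tiles.append(Tile(grid=sub, index=(r, c), parent_dims=(nz, ny, nx)))
    return tiles
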