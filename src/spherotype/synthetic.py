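"""Synthetic 5-channel spheroid z-stacks with a known cell roster.

Emulates mixed fibroblast/tumor spheroids imaged by confocal microscopy with
a nuclear counterstain (dapi), a non-specific reflectance channel, a
transmission channel, and two reference fluorescence channels (green =
fibroblasts, red = tumor cells).  The generator exists so that every
downstream stage — segmentation, ground-truth assignment, CNN training,
recapitulation — can be tested against an exact roster without external data.

The class-distinguishing signal lives in the reflectance texture: fibroblast
cytoplasm is rendered smoother/elongated, tumor cytoplasm more granular and
higher-contrast, with both the correlation-length and the amplitude gap
scaled by ``texture_effect`` (0 = classes identical in distribution, 1 =
maximal separation).  Transmission carries a weak attenuation-depth
difference, reference channels are perfectly class-specific by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import DEFAULT_VOXEL_SIZE, LabelVolume, VoxelGrid


class PlacementError(RuntimeError):
    """Cells could not be placed at the requested separation."""


@dataclass
class SpheroidSpec:
    """Parameters of one synthetic spheroid image.

    All lengths are micrometres.  Defaults mirror the acquisition geometry the
    pipeline targets: 4 um z-step, 0.8 um in-plane pixels, ~96 um stack.
    """

    n_cells: int = 30
    fibroblast_fraction: float = 0.5  # co-culture seeded 1:1
    spheroid_radius_um: float = 60.0
    nucleus_radius_um: tuple[float, float] = (4.0, 0.5)   # (mean, sd)
    cell_radius_um: tuple[float, float] = (7.0, 0.8)      # (mean, sd)
    texture_effect: float = 1.0
    transmission_effect: float | None = None  # None -> 0.3 * texture_effect
    stain_halo_um: float = 2.5  # reference dye fills the whole cell, slightly
                                # beyond the reflectance-bright cytoskeleton
    noise_sd: float = 100.0
    interface_artifact: bool = True
    stack_height_um: float = 96.0
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    lateral_px: int | None = None  # None -> sized to fit the spheroid
    min_separation_um: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.fibroblast_fraction <= 1.0:
            raise ValueError("fibroblast_fraction must be in [0, 1]")
        for r in (self.spheroid_radius_um, self.nucleus_radius_um[0], self.cell_radius_um[0]):
            if r <= 0:
                raise ValueError("radii must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        dz, dy, dx = self.voxel_size
        nz = max(int(round(self.stack_height_um / dz)), 4)
        if self.lateral_px is not None:
            ny = nx = int(self.lateral_px)
        else:
            margin = 2.5 * self.cell_radius_um[0]
            ny = nx = int(np.ceil(2 * (self.spheroid_radius_um + margin) / dy))
        return nz, ny, nx


@dataclass
class CellGroundTruth:
    """Roster entry for one simulated cell (voxel coordinates, 0-based)."""

    cell_id: int
    center: tuple[float, float, float]  # (z, y, x) in voxels
    type: str                           # 'fibroblast' | 'tumor'
    nucleus_radius_um: float
    cell_radius_um: float
    nucleus_radius_vox: tuple[float, float, float] = field(default=(0, 0, 0))
    cell_radius_vox: tuple[float, float, float] = field(default=(0, 0, 0))


FIBROBLAST = "fibroblast"
TUMOR = "tumor"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _place_centers(spec: SpheroidSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample physical (z,y,x) um positions inside the spheroid
    ellipsoid with a minimum pairwise separation."""
    dz, dy, dx = spec.voxel_size
    nz, ny, nx = spec.dims
    # usable z band keeps whole cell bodies off the top/bottom interface planes
    z_margin = spec.cell_radius_um[0] * 2.0 + dz
    z_lo, z_hi = z_margin, spec.stack_height_um - z_margin
    if z_hi <= z_lo:
        z_lo = z_hi = spec.stack_height_um / 2.0
    cz = spec.stack_height_um / 2.0
    cy, cx = ny * dy / 2.0, nx * dx / 2.0
    rz = max((z_hi - z_lo) / 2.0, dz / 2)
    rlat = min(spec.spheroid_radius_um, cy - spec.cell_radius_um[0] * 1.5)
    placed: list[np.ndarray] = []
    max_attempts = 400 * spec.n_cells
    attempts = 0
    while len(placed) < spec.n_cells and attempts < max_attempts:
        attempts += 1
        u = rng.uniform(-1, 1, size=3)
        if (u**2).sum() > 1.0:
            continue
        pos = np.array([cz + u[0] * rz, cy + u[1] * rlat, cx + u[2] * rlat])
        if not (z_lo <= pos[0] <= z_hi):
            continue
        ok = all(np.linalg.norm(pos - q) >= spec.min_separation_um for q in placed)
        if ok:
            placed.append(pos)
    if len(placed) < spec.n_cells:
        raise PlacementError(
            f"placed only {len(placed)}/{spec.n_cells} cells at separation "
            f"{spec.min_separation_um} um; reduce n_cells or separation"
        )
    return np.array(placed)


def _make_roster(spec: SpheroidSpec, rng: np.random.Generator) -> list[CellGroundTruth]:
    centers_um = _place_centers(spec, rng)
    dz, dy, dx = spec.voxel_size
    n_fib = _round_half_up(spec.n_cells * spec.fibroblast_fraction)
    types = [FIBROBLAST] * n_fib + [TUMOR] * (spec.n_cells - n_fib)
    rng.shuffle(types)
    roster = []
    for i, (pos, ctype) in enumerate(zip(centers_um, types)):
        rn = max(float(rng.normal(*spec.nucleus_radius_um)), 1.5)
        rc = max(float(rng.normal(*spec.cell_radius_um)), rn + 1.0)
        roster.append(
            CellGroundTruth(
                cell_id=i + 1,
                center=(pos[0] / dz, pos[1] / dy, pos[2] / dx),
                type=ctype,
                nucleus_radius_um=rn,
                cell_radius_um=rc,
                nucleus_radius_vox=(rn / dz, rn / dy, rn / dx),
                cell_radius_vox=(rc / dz, rc / dy, rc / dx),
            )
        )
    return roster


def _cell_bbox(center_vox, radius_um, voxel_size, dims):
    """Inclusive-exclusive slice bounds around a physical-radius ball."""
    slc = []
    for ax in range(3):
        r_vox = radius_um / voxel_size[ax]
        lo = max(int(np.floor(center_vox[ax] - r_vox)) - 1, 0)
        hi = min(int(np.ceil(center_vox[ax] + r_vox)) + 2, dims[ax])
        slc.append(slice(lo, hi))
    return tuple(slc)


def _phys_dist_sq(slc, center_vox, voxel_size):
    """Squared physical distance (um^2) of voxel centers in a bbox from a point."""
    axes = []
    for ax in range(3):
        idx = np.arange(slc[ax].start, slc[ax].stop, dtype=np.float64)
        axes.append((idx - center_vox[ax]) * voxel_size[ax])
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return zz**2 + yy**2 + xx**2


def paint_bodies(roster: list[CellGroundTruth], dims, voxel_size) -> np.ndarray:
    """Exclusive cell-body ownership volume (0 background, else cell_id).

    Overlapping bodies are resolved to the nearest center in physical
    distance; exact ties go to the lower cell_id (deterministic).
    """
    owner = np.zeros(dims, dtype=np.int32)
    best = np.full(dims, np.inf, dtype=np.float64)
    for cell in roster:
        slc = _cell_bbox(cell.center, cell.cell_radius_um, voxel_size, dims)
        d2 = _phys_dist_sq(slc, cell.center, voxel_size)
        inside = d2 <= cell.cell_radius_um**2
        take = inside & (d2 < best[slc])
        owner[slc][take] = cell.cell_id
        best[slc][take] = d2[take]
    return owner


def roster_to_reference_labels(
    roster: list[CellGroundTruth], dims, voxel_size=DEFAULT_VOXEL_SIZE
) -> LabelVolume:
    """Perfect-segmentation oracle: voxel-painted cell bodies as labels."""
    return LabelVolume(labels=paint_bodies(roster, tuple(dims), voxel_size).astype(np.int64),
                       voxel_size=voxel_size)


def _smooth_noise(rng, dims, sigma_um, voxel_size) -> np.ndarray:
    """Unit-variance band-limited noise field with physical correlation length."""
    raw = rng.standard_normal(dims)
    sig_vox = [max(s / v, 1e-3) for s, v in zip(sigma_um, voxel_size)]
    f = ndimage.gaussian_filter(raw, sigma=sig_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


# rendering amplitudes (16-bit scale); chosen once to resemble confocal data:
# bright nuclei, mid-range reflectance with low matrix speckle, bright-field
# transmission near mid-scale, saturating reference stains.
_AMP = {
    "dapi": 40000.0,
    "refl_body": 12000.0,
    "refl_texture": 4000.0,
    "refl_speckle": 500.0,
    "interface": 18000.0,
    "trans_bg": 30000.0,
    "trans_atten": 8000.0,
    "stain": 25000.0,
    "baseline": 100.0,
}


def generate_spheroid(spec: SpheroidSpec) -> tuple[VoxelGrid, list[CellGroundTruth]]:
    """Render one synthetic spheroid stack plus its roster.

    Deterministic for a fixed ``spec.seed`` (bit-exact).  Returns a 5-channel
    uint16 :class:`VoxelGrid` (dapi, reflectance, transmission, green, red).
    """
    rng = np.random.default_rng(spec.seed)
    dims = spec.dims
    vs = spec.voxel_size
    roster = _make_roster(spec, rng)
    owner = paint_bodies(roster, dims, vs)
    effect = float(spec.texture_effect)
    t_effect = (0.3 * effect) if spec.transmission_effect is None else float(spec.transmission_effect)

    fib_mask = np.isin(owner, [c.cell_id for c in roster if c.type == FIBROBLAST])
    tum_mask = np.isin(owner, [c.cell_id for c in roster if c.type == TUMOR])

    dapi = np.full(dims, _AMP["baseline"], dtype=np.float64)
    refl = np.full(dims, _AMP["baseline"], dtype=np.float64)
    trans = np.full(dims, _AMP["trans_bg"], dtype=np.float64)
    green = np.zeros(dims, dtype=np.float64)
    red = np.zeros(dims, dtype=np.float64)

    # class-conditional cytoplasmic textures: correlation length and contrast
    # both interpolate with texture_effect; identical at effect = 0
    base_sig = (1.6, 2.0, 2.0)
    fib_sig = tuple(s * (1.0 + 1.2 * effect) for s in base_sig)
    tum_sig = tuple(s / (1.0 + 1.2 * effect) for s in base_sig)
    fib_amp = _AMP["refl_texture"] * (1.0 - 0.8 * effect)
    tum_amp = _AMP["refl_texture"] * (1.0 + 0.8 * effect)
    fib_tex = _smooth_noise(rng, dims, fib_sig, vs)
    tum_tex = _smooth_noise(rng, dims, tum_sig, vs)

    # per-cell rendering within exclusive ownership regions; the reference
    # stain fills the whole cell out to a small halo beyond the
    # reflectance-bright cytoskeleton, never crossing into another cell
    for cell in roster:
        r_stain = cell.cell_radius_um + spec.stain_halo_um
        slc = _cell_bbox(cell.center, r_stain, vs, dims)
        own = owner[slc] == cell.cell_id
        d2 = _phys_dist_sq(slc, cell.center, vs)
        # nucleus: anisotropic Gaussian, sigma ~ 2/3 of nuclear radius
        sig = cell.nucleus_radius_um / 1.5
        dapi[slc] += _AMP["dapi"] * np.exp(-d2 / (2 * sig**2))
        # cytoplasm: radial profile 1 -> 0.5 at the membrane
        profile = np.where(own, 1.0 - 0.5 * d2 / cell.cell_radius_um**2, 0.0)
        refl[slc] += _AMP["refl_body"] * profile
        trans[slc] -= _AMP["trans_atten"] * profile * (
            1.0 + (0.5 if cell.type == TUMOR else -0.5) * t_effect
        )
        stain_region = (d2 <= r_stain**2) & (own | (owner[slc] == 0))
        stain = _AMP["stain"] * np.where(stain_region, 1.0 - 0.5 * d2 / r_stain**2, 0.0)
        if cell.type == FIBROBLAST:
            green[slc] += stain
        else:
            red[slc] += stain

    refl += fib_amp * fib_tex * fib_mask + tum_amp * tum_tex * tum_mask
    # non-specific low-amplitude matrix speckle everywhere
    refl += _AMP["refl_speckle"] * _smooth_noise(rng, dims, (1.0, 1.0, 1.0), vs)

    if spec.interface_artifact:
        # bright reflectance at the gel-glass interfaces (top/bottom planes)
        for plane in (0, dims[0] - 1):
            pat = rng.standard_normal(dims[1:])
            pat = ndimage.gaussian_filter(pat, sigma=2.0)
            pat = (pat - pat.min()) / max(float(np.ptp(pat)), 1e-9)
            refl[plane] += _AMP["interface"] * (0.4 + 0.6 * pat)

    channels = {"dapi": dapi, "reflectance": refl, "transmission": trans,
                "green": green, "red": red}
    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = channels[name] + rng.normal(0.0, spec.noise_sd, dims)
    out = {
        name: np.clip(np.rint(v), 0, 65535).astype(np.uint16)
        for name, v in channels.items()
    }
    return VoxelGrid(channels=out, voxel_size=vs), roster


def match_rois_to_roster(rois, reference: LabelVolume) -> dict[int, int | None]:
    """Match segmented ROIs to roster cells by majority voxel overlap.

    Each ROI maps to the roster cell owning the majority of the ROI voxels
    that fall inside any reference cell body; ROIs that touch no body at all
    map to None (false positives).
    """
    out: dict[int, int | None] = {}
    lab = reference.labels
    for roi in rois:
        vz, vy, vx = roi.voxels.T
        vals = lab[vz, vy, vx]
        vals = vals[vals > 0]
        out[roi.label_id] = int(np.bincount(vals).argmax()) if vals.size else None
    return out


def roster_to_dataframe(roster: list[CellGroundTruth]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "z": c.center[0], "y": c.center[1], "x": c.center[2],
                "type": c.type,
                "nucleus_radius_um": c.nucleus_radius_um,
                "cell_radius_um": c.cell_radius_um,
            }
            for c in roster
        ]
    )


def roster_from_dataframe(df) -> list[CellGroundTruth]:
    roster = []
    for row in df.itertuples(index=False):
        roster.append(
            CellGroundTruth(
                cell_id=int(row.cell_id),
                center=(float(row.z), float(row.y), float(row.x)),
                type=str(row.type),
                nucleus_radius_um=float(row.nucleus_radius_um),
                cell_radius_um=float(row.cell_radius_um),
            )
        )
    return roster


def multi_image_rosters(
    n_images: int, base_spec: SpheroidSpec, seed: int, n_cells_spread: int = 0
) -> list[tuple[str, VoxelGrid, list[CellGroundTruth]]]:
    """Generate several independent spheroid images (distinct seeds) as the
    multi-image corpus needed for strict hold-out experiments.

    ``n_cells_spread`` grades image sizes from ``n_cells`` up to
    ``n_cells + n_cells_spread`` (real spheroids vary in cellularity).
    """
    out = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_images)]
    for i, s in enumerate(child_seeds):
        extra = (i * n_cells_spread) // max(n_images - 1, 1) if n_cells_spread else 0
        spec = replace(base_spec, seed=s, n_cells=base_spec.n_cells + extra)
        grid, roster = generate_spheroid(spec)
        out.append((f"image_{i:03d}", grid, roster))
    return out
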