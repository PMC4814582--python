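"""Synthetic phantoms and tiled light-sheet acquisition simulation.

A tiled acquisition displaces a short, thin sheet along its propagation axis
and records one full 3D stack per tile position; only the well-focused
central portion of each tile is kept at reconstruction time.  During a
z-stack the sheet moves together with the detection focal plane, so for a
static object the recorded stack is a single 3D convolution with the
*system* PSF (detection PSF weighted along z by the sheet's waist profile),
while the sheet's axial envelope — its falloff along the propagation axis
away from the tile centre — multiplies the object in sample space:

    stack = camera( (phantom × envelope(x − tile)) ⊗ PSF_system )

followed by an sCMOS-style camera: photon scaling, Poisson shot noise,
Gaussian read noise and a constant offset.  The factorization uses the
waist z-profile for the whole tile (the sheet does thicken towards the tile
edges; that is exactly why reconstruction keeps only tile centres).  Phantoms stand in for the labelled embryos of a real
experiment: random sub-diffraction beads (for resolution measurements) or
spherical membrane/nucleus shells (for structure).  All randomness is seeded
and reproducible.

Array convention: camera-facing stacks and phantoms are indexed ``[z, y, x]``
(z = detection axis, x = propagation axis), voxel sizes in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .wave_optics import Psf3D, SheetProfile

__all__ = [
    "Phantom",
    "TilingPlan",
    "CameraModel",
    "TiledStack",
    "plan_tiling",
    "bead_phantom",
    "shell_phantom",
    "illumination_from_sheet",
    "simulate_tile",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class Phantom:
    """Fluorophore density on a camera-aligned grid.

    ``density`` is nonnegative, indexed [z, y, x]; ``centers`` records
    ground-truth object centres in um (z, y, x), relative to the volume
    centre, when the phantom kind provides them.
    """

    density: np.ndarray
    voxel: tuple[float, float, float]  # (dz, dy, dx) um
    kind: str
    seed: int
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 3 or np.any(d < 0):
            raise ValueError("density must be a nonnegative 3D array")
        object.__setattr__(self, "density", d)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centered voxel-coordinate axes (z, y, x) in um."""
        return tuple(
            (np.arange(s) - s // 2) * v for s, v in zip(self.density.shape, self.voxel)
        )


@dataclass(frozen=True)
class TilingPlan:
    """Ordered axial tile centres with uniform spacing."""

    positions: tuple[float, ...]  # um along the propagation axis
    spacing: float
    sheet_length: float

    def __post_init__(self) -> None:
        p = np.asarray(self.positions)
        if p.size == 0:
            raise ValueError("a tiling plan needs at least one position")
        if p.size > 1 and not np.allclose(np.diff(p), self.spacing):
            raise ValueError("positions must be uniformly spaced by `spacing`")

    @property
    def n_tiles(self) -> int:
        return len(self.positions)


def plan_tiling(fov_extent: float, sheet_length: float, spacing: float) -> TilingPlan:
    """Minimal uniformly spaced tile positions covering a field of view.

    ``n_tiles = 1 + ceil((fov_extent − sheet_length)/spacing)`` when the FOV
    exceeds the sheet length, else a single tile; positions are centred on
    the FOV.  Spacing larger than the sheet length would leave coverage gaps
    and is rejected.
    """
    if fov_extent <= 0 or sheet_length <= 0 or spacing <= 0:
        raise ValueError("fov_extent, sheet_length and spacing must be positive")
    if spacing > sheet_length:
        raise ValueError(
            f"tile spacing {spacing} um exceeds the sheet length {sheet_length} um: "
            "coverage gap"
        )
    if fov_extent <= sheet_length:
        n = 1
    else:
        n = 1 + math.ceil((fov_extent - sheet_length) / spacing)
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    return TilingPlan(tuple(offsets), spacing, sheet_length)


def _insert_sphere(density: np.ndarray, voxel, center, radius, value=1.0, shell=0.0):
    """Add a solid sphere (or spherical shell of thickness ``shell``) in place."""
    dz, dy, dx = voxel
    shape = density.shape
    zc, yc, xc = center
    # bounding box in voxels
    pad = radius + shell + max(voxel)
    z0 = max(0, int((zc - pad) / dz + shape[0] // 2))
    z1 = min(shape[0], int((zc + pad) / dz + shape[0] // 2) + 2)
    y0 = max(0, int((yc - pad) / dy + shape[1] // 2))
    y1 = min(shape[1], int((yc + pad) / dy + shape[1] // 2) + 2)
    x0 = max(0, int((xc - pad) / dx + shape[2] // 2))
    x1 = min(shape[2], int((xc + pad) / dx + shape[2] // 2) + 2)
    z = (np.arange(z0, z1) - shape[0] // 2) * dz - zc
    y = (np.arange(y0, y1) - shape[1] // 2) * dy - yc
    x = (np.arange(x0, x1) - shape[2] // 2) * dx - xc
    r = np.sqrt(z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2)
    if shell > 0:
        hit = np.abs(r - radius) <= shell / 2.0
    else:
        hit = r <= radius
    density[z0:z1, y0:y1, x0:x1][hit] += value


def bead_phantom(
    n_beads: int,
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    bead_radius: float = 0.05,
    min_separation: float = 2.0,
    margin: float = 1.0,
    seed: int = 0,
    intensity: float = 1.0,
) -> Phantom:
    """Randomly placed sub-diffraction beads with recorded ground-truth centres.

    Bead positions keep ``min_separation`` um between centres and ``margin``
    um from the volume faces.  A bead smaller than a voxel is deposited as a
    single-voxel impulse of the requested integrated intensity.
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel
    half = [(s // 2) * v for s, v in zip(shape, voxel)]
    lo = [-h + margin for h in half]
    hi = [
        (s - 1 - s // 2) * v - margin for s, v in zip(shape, voxel)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        raise ValueError("volume too small for the requested margin")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 1000 * n_beads:
            raise ValueError("could not place beads with the requested separation")
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - p) >= min_separation for p in centers):
            centers.append(c)
    density = np.zeros(shape)
    for c in centers:
        if bead_radius < min(voxel):
            iz = int(round(c[0] / dz)) + shape[0] // 2
            iy = int(round(c[1] / dy)) + shape[1] // 2
            ix = int(round(c[2] / dx)) + shape[2] // 2
            density[iz, iy, ix] += intensity
        else:
            _insert_sphere(density, voxel, c, bead_radius, intensity)
    return Phantom(density, voxel, "beads", seed, np.asarray(centers))


def shell_phantom(
    n_cells: int,
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    radius_range: tuple[float, float] = (2.0, 4.0),
    membrane_thickness: float = 0.4,
    nuclear_spots: bool = True,
    nuclear_radius: float = 1.0,
    seed: int = 0,
) -> Phantom:
    """Membrane-like spherical shells with optional solid nuclear spots.

    Emulates membrane/nucleus double labelling at desk scale.  Rejects
    requests that would pack more than half the volume with cells.
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel
    vol_um3 = np.prod([s * v for s, v in zip(shape, voxel)])
    r_max = radius_range[1]
    if n_cells * (4 / 3) * math.pi * r_max**3 > 0.5 * vol_um3:
        raise ValueError("requested cells would pack more than half the volume")
    half = [(s // 2) * v for s, v in zip(shape, voxel)]
    density = np.zeros(shape)
    centers = []
    for _ in range(n_cells):
        r = rng.uniform(*radius_range)
        c = rng.uniform([-h + r for h in half], [h - r for h in half])
        _insert_sphere(density, voxel, c, r, 1.0, shell=membrane_thickness)
        if nuclear_spots:
            _insert_sphere(density, voxel, c, min(nuclear_radius, r / 2), 1.0)
        centers.append(c)
    return Phantom(density, voxel, "shells", seed, np.asarray(centers))


@dataclass(frozen=True)
class CameraModel:
    """sCMOS-style camera: photon scaling, shot noise, read noise, offset."""

    photons_per_unit: float = 100.0
    read_noise: float = 1.5  # counts rms
    offset: float = 100.0  # counts
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise < 0 or self.photons_per_unit <= 0:
            raise ValueError("invalid camera parameters")

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise == 0

    def expose(self, flux: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Convert a noiseless flux field (density units) to camera counts."""
        counts = self.photons_per_unit * np.clip(flux, 0.0, None)
        if self.shot_noise or self.read_noise > 0:
            rng = np.random.default_rng(self.seed) if rng is None else rng
            if self.shot_noise:
                counts = rng.poisson(counts).astype(float)
            if self.read_noise > 0:
                counts = counts + rng.normal(0.0, self.read_noise, counts.shape)
        return counts + self.offset


@dataclass(frozen=True)
class TiledStack:
    """Per-tile 3D stacks plus the geometry needed to reconstruct them."""

    tiles: tuple[np.ndarray, ...]  # each [z, y, x]
    plan: TilingPlan
    voxel: tuple[float, float, float]
    camera: CameraModel
    exposures_per_plane: int = 1

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.tiles}
        if len(shapes) != 1:
            raise ValueError("all tiles must share one shape")
        if len(self.tiles) != self.plan.n_tiles:
            raise ValueError("tile count must match the plan")


def sheet_envelope(
    sheet: SheetProfile,
    n_x: int,
    dx: float,
    tile_position: float,
) -> np.ndarray:
    """Sheet axial uniformity I(x − tile, z≈0), resampled, unit peak.

    This is the sample-space illumination weight along the propagation axis:
    structures away from the tile centre are excited by a weaker (and in
    reality thicker) part of the sheet.
    """
    iz0 = int(np.argmin(np.abs(sheet.z_coords)))
    x = (np.arange(n_x) - n_x // 2) * dx - tile_position
    env = np.interp(x, sheet.x_coords, sheet.intensity[:, iz0], left=0.0, right=0.0)
    if env.max() <= 0:
        raise ValueError("sheet profile does not cover the phantom extent")
    return env / env.max()


def simulate_tile(
    phantom: Phantom,
    sheet: SheetProfile,
    det_psf: Psf3D,
    camera: CameraModel,
    tile_position: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Image one tile: weight by the sheet envelope, blur with the system
    PSF (sheet waist z-profile × detection PSF), expose plane by plane.

    Deterministic (bit-identical) in noiseless mode; with noise enabled the
    caller controls the stream via ``rng`` (fresh, seeded from the camera
    seed, when omitted).
    """
    if det_psf.voxel != phantom.voxel:
        raise ValueError(
            f"PSF voxel {det_psf.voxel} does not match phantom voxel {phantom.voxel}"
        )
    from .wave_optics import system_psf

    env = sheet_envelope(sheet, phantom.density.shape[2], phantom.voxel[2], tile_position)
    excited = phantom.density * env[None, None, :]
    psf_sys = system_psf(sheet, det_psf, tile_center_x=0.0)
    blurred = fftconvolve(excited, psf_sys.data, mode="same")
    blurred = np.clip(blurred, 0.0, None)  # FFT ringing can dip barely below 0
    return camera.expose(blurred, rng)


def simulate_acquisition(
    phantom: Phantom,
    plan: TilingPlan,
    sheet: SheetProfile,
    det_psf: Psf3D,
    camera: CameraModel,
) -> TiledStack:
    """Acquire one stack per tile position.

    Every plane of the field of view is exposed once per tile, so the total
    illumination (and acquisition time) grows linearly with the tile count —
    the cost side of trading temporal resolution for field of view.
    """
    half_fov = (max(abs(p) for p in plan.positions) if plan.positions else 0.0)
    nx = phantom.density.shape[2]
    x_extent = nx * phantom.voxel[2]
    if half_fov + plan.sheet_length / 2 > x_extent:
        raise ValueError("tiling plan extends beyond the phantom grid")
    rng = np.random.default_rng(camera.seed)
    tiles = tuple(
        simulate_tile(phantom, sheet, det_psf, camera, pos, rng) for pos in plan.positions
    )
    return TiledStack(tiles, plan, phantom.voxel, camera, exposures_per_plane=plan.n_tiles)
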