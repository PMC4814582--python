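"""Binary SLM phase-map synthesis for generating, shaping and tiling light sheets.

A single binary spatial light modulator (SLM) conjugate to the excitation
objective's rear pupil can emulate an arbitrary annular amplitude mask and, at
the same time, refocus ("tile") the beam along its propagation axis:

* the pupil is split into a *retain* area (the designed annulus) and an
  *abandon* area carrying a high-frequency 0/π grating that diffracts unwanted
  light far off-axis, where a slit blocks it;
* a continuous defocus (spherical) phase ``φ(r) = (2π/λ)·d·√(n² − NA(r)²)``
  displaces the focus by ``d`` along the propagation axis;
* a Dammann grating multiplexes the beam into an array of equal-intensity
  beams for dithered (lower peak intensity) sheets;
* because the SLM is binary, continuous designs are binarized to {0, π},
  which creates conjugate diffraction orders; a lateral carrier tilt is added
  so the slit can select the designed order (see :mod:`tilesheet.wave_optics`).

All phase maps are plain ``float64`` arrays in radians on an :class:`SlmGrid`;
binary maps take values in exactly ``{0, π}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHASE_LEVELS",
    "SlmGrid",
    "PupilCalibration",
    "AnnulusSpec",
    "TilingShift",
    "DammannSpec",
    "PhaseMapContinuous",
    "PhaseMapBinary",
    "transition_count",
    "spherical_phase_map",
    "carrier_phase",
    "binarize_phase",
    "annulus_retain_mask",
    "abandon_grating",
    "compose_retain_abandon",
    "dammann_phase",
    "dammann_tiled_map",
    "bessel_tiled_map",
    "coherent_array_map",
]

#: Phase levels a binary SLM can display, in radians.
PHASE_LEVELS = (0.0, math.pi)


@dataclass(frozen=True)
class SlmGrid:
    """Pixel geometry of a binary SLM (defaults: 1,280 x 1,024, 13.62 um pitch)."""

    n_cols: int = 1280
    n_rows: int = 1024
    pixel_pitch: float = 13.62  # um per pixel

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("SLM grid needs at least 2x2 pixels")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered pixel indices (rows, cols) as a broadcastable pair.

        The centre sits on the pixel ``n // 2`` so that maps evaluated here
        line up exactly with the FFT origin under ``ifftshift``.
        """
        r = np.arange(self.n_rows) - self.n_rows // 2
        c = np.arange(self.n_cols) - self.n_cols // 2
        return r[:, None].astype(float), c[None, :].astype(float)


@dataclass(frozen=True)
class PupilCalibration:
    """Linear map from SLM pixel radius to numerical aperture.

    ``NA(pixel) = na_per_px * radius_px``.  The relay magnification between
    the SLM and the objective rear pupil fixes this constant in hardware; in
    the simulator it is a free calibration value.  NA here is absolute
    (includes the medium index, so a water objective can reach NA = 1.33).
    """

    na_per_px: float

    def __post_init__(self) -> None:
        if self.na_per_px <= 0:
            raise ValueError("na_per_px must be positive")

    def na_radius(self, grid: SlmGrid) -> np.ndarray:
        """Radial NA coordinate of every pixel of ``grid``."""
        r, c = grid.pixel_coords()
        return self.na_per_px * np.hypot(r, c)

    def na_axes(self, grid: SlmGrid) -> tuple[np.ndarray, np.ndarray]:
        """Per-axis NA coordinates (na_row, na_col), broadcastable."""
        r, c = grid.pixel_coords()
        return self.na_per_px * r, self.na_per_px * c

    def na_max(self, grid: SlmGrid) -> float:
        """Largest NA representable on the inscribed pupil circle."""
        return self.na_per_px * min(grid.n_rows, grid.n_cols) / 2.0


@dataclass(frozen=True)
class AnnulusSpec:
    """Annular pupil: inner/outer numerical aperture (absolute, n included)."""

    na_inner: float
    na_outer: float

    def __post_init__(self) -> None:
        if not 0 <= self.na_inner < self.na_outer:
            raise ValueError(
                f"need 0 <= na_inner < na_outer, got {self.na_inner}, {self.na_outer}"
            )


@dataclass(frozen=True)
class TilingShift:
    """Signed focus displacement along the propagation axis, in um."""

    displacement: float = 0.0


def transition_count(n_beams: int) -> int:
    """Transition points per period of a Dammann grating for ``n_beams`` orders.

    ``2 * int((N - 1) / 4) + 2`` for N >= 3; the N = 1 grating is unmodulated
    and needs none.
    """
    if n_beams < 1 or n_beams % 2 == 0:
        raise ValueError("n_beams must be an odd positive integer")
    if n_beams == 1:
        return 0
    return 2 * ((n_beams - 1) // 4) + 2


@dataclass(frozen=True)
class DammannSpec:
    """A binary Dammann grating: ``n_beams`` equal-intensity diffraction orders.

    ``transitions`` are the fractional positions within one period where the
    0/π phase toggles; the profile starts at phase 0.
    """

    n_beams: int
    period_px: int
    transitions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_beams >= 3:
            expected = transition_count(self.n_beams)
            if len(self.transitions) != expected:
                raise ValueError(
                    f"{self.n_beams}-beam grating needs {expected} transitions, "
                    f"got {len(self.transitions)}"
                )
        t = np.asarray(self.transitions)
        if t.size and (np.any(t < 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0)):
            raise ValueError("transitions must be strictly increasing in [0, 1)")
        if t.size and self.period_px * np.min(np.diff(np.r_[t, 1 + t[0]])) < 1.0:
            raise ValueError(
                f"transitions closer than one pixel at period {self.period_px}; "
                f"minimum feasible period is "
                f"{math.ceil(1.0 / np.min(np.diff(np.r_[t, 1 + t[0]])))} px"
            )

    def profile(self, n_px: int | None = None) -> np.ndarray:
        """One period of the grating phase, sampled on ``n_px`` pixels."""
        n_px = self.period_px if n_px is None else n_px
        x = (np.arange(n_px) + 0.5) / n_px
        n_flips = np.zeros(n_px, dtype=int)
        for t in self.transitions:
            n_flips += x >= t
        return np.where(n_flips % 2, math.pi, 0.0)


@dataclass(frozen=True)
class PhaseMapContinuous:
    """Continuous phase in [0, 2π) on an SLM grid."""

    values: np.ndarray
    grid: SlmGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if np.any(v < 0) or np.any(v >= 2 * math.pi):
            raise ValueError("continuous phase must lie in [0, 2*pi)")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PhaseMapBinary:
    """Binary {0, π} phase map on an SLM grid, with a free-text provenance."""

    values: np.ndarray
    grid: SlmGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isin(v, PHASE_LEVELS)):
            raise ValueError("binary phase map may only contain 0 and pi")
        object.__setattr__(self, "values", v)


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to [0, 2π), guarding against 2π round-off landing on the edge."""
    w = np.mod(phase, 2 * math.pi)
    w[w >= 2 * math.pi - 1e-12] = 0.0
    return w


def max_representable_shift(
    annulus: AnnulusSpec,
    grid: SlmGrid,
    calibration: PupilCalibration,
    wavelength: float,
    medium_index: float,
) -> float:
    """Largest defocus |d| before the phase aliases (Nyquist: < π per pixel).

    The defocus fringe is steepest at the annulus outer edge, where
    ``|dφ/d(na)| = (2π/λ)·d·na/√(n² − na²)``.
    """
    na = annulus.na_outer
    slope = (2 * math.pi / wavelength) * na / math.sqrt(medium_index**2 - na**2)
    return math.pi / (slope * calibration.na_per_px)


def spherical_phase_map(
    shift: TilingShift,
    annulus: AnnulusSpec,
    grid: SlmGrid,
    calibration: PupilCalibration,
    wavelength: float,
    medium_index: float = 1.33,
) -> PhaseMapContinuous:
    """Defocus phase that displaces the focus by ``shift.displacement`` um.

    Uses the exact high-NA kernel ``φ = (2π/λ)·d·√(n² − NA²)`` (the axial
    wavevector times the displacement), referenced to the annulus centre so
    the map is zero there and stays slowly varying across the ring.  Raises
    if the requested shift aliases on the pixel grid.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if annulus.na_outer >= medium_index:
        raise ValueError("annulus outer NA must be below the medium index")
    d = shift.displacement
    if d != 0.0:
        d_max = max_representable_shift(annulus, grid, calibration, wavelength, medium_index)
        if abs(d) > d_max:
            raise ValueError(
                f"displacement {d} um aliases on this grid; maximum representable "
                f"shift is {d_max:.2f} um"
            )
    na = calibration.na_radius(grid)
    na_mid = 0.5 * (annulus.na_inner + annulus.na_outer)
    kz = np.sqrt(np.clip(medium_index**2 - na**2, 0.0, None))
    kz_ref = math.sqrt(medium_index**2 - na_mid**2)
    # sign: exp(iφ)·exp(i·k_x·x) is stationary at x = +d, i.e. a positive
    # displacement moves the focus downstream along the propagation axis
    phase = -(2 * math.pi / wavelength) * d * (kz - kz_ref)
    if d == 0.0:
        phase = np.zeros(grid.shape)
    return PhaseMapContinuous(_wrap(phase), grid)


def carrier_phase(
    grid: SlmGrid,
    calibration: PupilCalibration,
    wavelength: float,
    offset_um: float,
    axis: int = 0,
) -> np.ndarray:
    """Linear pupil tilt that displaces the focus laterally by ``offset_um``.

    Binarizing a designed phase creates a conjugate (mirror) diffraction
    order; a carrier tilt separates designed and conjugate orders laterally
    in the image-conjugate plane so that the optical slit can pass one.
    ``axis=0`` tilts along rows (the dither axis by convention).
    """
    na_r, na_c = calibration.na_axes(grid)
    na_lin = na_r if axis == 0 else na_c
    return np.broadcast_to(
        (2 * math.pi / wavelength) * offset_um * na_lin, grid.shape
    ).copy()


def binarize_phase(cont: PhaseMapContinuous, provenance: str = "") -> PhaseMapBinary:
    """Reset a continuous phase to the two SLM levels.

    Values in [0, π) map to 0; values in [π, 2π) map to π.
    """
    binary = np.where(cont.values < math.pi, 0.0, math.pi)
    return PhaseMapBinary(binary, cont.grid, provenance)


def annulus_retain_mask(
    annulus: AnnulusSpec, grid: SlmGrid, calibration: PupilCalibration
) -> np.ndarray:
    """Boolean mask, true where ``na_inner <= NA(pixel) <= na_outer``."""
    if annulus.na_inner > calibration.na_max(grid):
        raise ValueError(
            f"annulus (inner NA {annulus.na_inner}) lies entirely outside the "
            f"grid extent (max NA {calibration.na_max(grid):.3f})"
        )
    na = calibration.na_radius(grid)
    return (na >= annulus.na_inner) & (na <= annulus.na_outer)


def abandon_grating(grid: SlmGrid, period_px: int = 2) -> PhaseMapBinary:
    """High-frequency 0/π stripe grating for the abandon area.

    Stripes run along columns and alternate along the row (dither) axis with a
    50% duty cycle, so the 0th-order far-field amplitude ``mean(e^{iφ})``
    vanishes and the abandoned light is diverted off-axis to the slit.
    """
    if period_px < 2 or period_px % 2:
        raise ValueError("abandon grating period must be an even integer >= 2")
    rows = np.arange(grid.n_rows)
    stripe = np.where((rows // (period_px // 2)) % 2, math.pi, 0.0)
    values = np.broadcast_to(stripe[:, None], grid.shape).copy()
    return PhaseMapBinary(values, grid, f"abandon grating, period {period_px} px")


def compose_retain_abandon(
    retain_mask: np.ndarray,
    inner_pattern: PhaseMapBinary,
    grating: PhaseMapBinary,
) -> PhaseMapBinary:
    """Paste ``inner_pattern`` inside the retain area, the grating elsewhere."""
    if inner_pattern.grid != grating.grid or retain_mask.shape != inner_pattern.grid.shape:
        raise ValueError("retain mask, pattern and grating must share one grid")
    values = np.where(retain_mask, inner_pattern.values, grating.values)
    return PhaseMapBinary(
        values,
        inner_pattern.grid,
        f"retain[{inner_pattern.provenance}] + abandon[{grating.provenance}]",
    )


def dammann_phase(spec: DammannSpec, grid: SlmGrid, axis: int = 0) -> np.ndarray:
    """Tile the grating's period across the grid along ``axis`` (0 = rows)."""
    n = grid.n_rows if axis == 0 else grid.n_cols
    one = spec.profile()
    reps = -(-n // spec.period_px)
    line = np.tile(one, reps)[:n]
    if axis == 0:
        return np.broadcast_to(line[:, None], grid.shape).copy()
    return np.broadcast_to(line[None, :], grid.shape).copy()


def bessel_tiled_map(
    shift: TilingShift,
    annulus: AnnulusSpec,
    grid: SlmGrid,
    calibration: PupilCalibration,
    wavelength: float,
    medium_index: float = 1.33,
    carrier_offset_um: float = 0.0,
    abandon_period_px: int = 2,
) -> PhaseMapBinary:
    """Binary SLM map producing a single (optionally tiled) Bessel beam.

    Defocus plus carrier phase, binarized, inside the annular retain area;
    the abandon grating elsewhere.
    """
    cont = spherical_phase_map(shift, annulus, grid, calibration, wavelength, medium_index)
    total = cont.values
    if carrier_offset_um:
        total = total + carrier_phase(grid, calibration, wavelength, carrier_offset_um)
    inner = binarize_phase(
        PhaseMapContinuous(_wrap(total), grid),
        provenance=f"bessel d={shift.displacement}um NA {annulus.na_inner}/{annulus.na_outer}",
    )
    mask = annulus_retain_mask(annulus, grid, calibration)
    return compose_retain_abandon(mask, inner, abandon_grating(grid, abandon_period_px))


def dammann_tiled_map(
    spec: DammannSpec,
    shift: TilingShift,
    annulus: AnnulusSpec,
    grid: SlmGrid,
    calibration: PupilCalibration,
    wavelength: float,
    medium_index: float = 1.33,
    carrier_offset_um: float = 0.0,
    abandon_period_px: int = 2,
) -> PhaseMapBinary:
    """Binary SLM map producing a tiled incoherent beam array.

    The continuous sum (Dammann grating phase + defocus phase + carrier) is
    wrapped, binarized with :func:`binarize_phase`, and composed with the
    annular retain mask and the abandon grating.
    """
    total = dammann_phase(spec, grid, axis=0)
    total = total + spherical_phase_map(
        shift, annulus, grid, calibration, wavelength, medium_index
    ).values
    if carrier_offset_um:
        total = total + carrier_phase(grid, calibration, wavelength, carrier_offset_um)
    inner = binarize_phase(
        PhaseMapContinuous(_wrap(total), grid),
        provenance=(
            f"dammann {spec.n_beams} beams, d={shift.displacement}um, "
            f"NA {annulus.na_inner}/{annulus.na_outer}"
        ),
    )
    mask = annulus_retain_mask(annulus, grid, calibration)
    return compose_retain_abandon(mask, inner, abandon_grating(grid, abandon_period_px))


def coherent_array_map(
    n_beams: int,
    beam_spacing_um: float,
    annulus: AnnulusSpec,
    image_plane_grid: SlmGrid,
    image_pixel_um: float,
    pupil_grid: SlmGrid,
    pupil_calibration: PupilCalibration,
    wavelength: float,
    medium_index: float = 1.33,
    abandon_period_px: int = 2,
) -> tuple[PhaseMapBinary, PhaseMapBinary]:
    """Image-plane and pupil-plane maps for a coherent Bessel-beam array.

    The image-plane SLM displays the binarized phase of the target field — a
    sum of ``n_beams`` ideal Bessel beams (transverse profile ``J0(k·na_mid·r)``
    band-limited to the annulus) displaced along the dither axis — exactly as
    a lattice light sheet is written.  The pupil-plane SLM replaces the
    annular photo-mask: annulus retained, abandon grating elsewhere.

    Returns ``(image_map, pupil_map)``.  Warns (via ``ValueError`` only for
    unrepresentable spacing) when beams are closer than the annulus resolution
    limit, where strong interference is expected.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if beam_spacing_um < image_pixel_um:
        raise ValueError("beam spacing is not representable on the image-plane grid")
    k = 2 * math.pi / wavelength
    na_mid = 0.5 * (annulus.na_inner + annulus.na_outer)
    dna = 0.5 * (annulus.na_outer - annulus.na_inner)
    r_idx, c_idx = image_plane_grid.pixel_coords()
    y = r_idx * image_pixel_um  # dither axis
    z = c_idx * image_pixel_um  # detection axis
    offsets = (np.arange(n_beams) - (n_beams - 1) / 2.0) * beam_spacing_um
    from scipy.special import j0

    field = np.zeros(image_plane_grid.shape)
    for y0 in offsets:
        r = np.hypot(y - y0, z)
        # J0 carrier at the annulus centre NA, apodized by the annular
        # bandwidth (sinc envelope of the ring thickness)
        field += j0(k * na_mid * r) * np.sinc(k * dna * r / math.pi)
    phase = np.where(field >= 0, 0.0, math.pi)
    image_map = PhaseMapBinary(
        phase,
        image_plane_grid,
        f"coherent array {n_beams} beams @ {beam_spacing_um} um",
    )
    mask = annulus_retain_mask(annulus, pupil_grid, pupil_calibration)
    zero = PhaseMapBinary(np.zeros(pupil_grid.shape), pupil_grid, "annulus filter")
    pupil_map = compose_retain_abandon(
        mask, zero, abandon_grating(pupil_grid, abandon_period_px)
    )
    return image_map, pupil_map
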