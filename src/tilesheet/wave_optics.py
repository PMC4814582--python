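"""Scalar Fourier-optics propagation and light-sheet figures of merit.

The excitation pupil is sampled in absolute numerical-aperture coordinates
(``na = n·sinθ``, medium index included).  A pupil field ``P(na_y, na_z)``
propagates to the focal region by the angular spectrum of plane waves,

    E(y, z; x) = F⁻¹[ P · exp(i·k_x·x) ],   k_x = (2π/λ)·√(n² − na²),

with evanescent components (``na ≥ n``) excluded.  The propagation axis is
``x``, the scan/dither axis is ``y`` and the detection-objective axis is
``z`` — a swept (or dithered) light sheet is the incoherent time average of
the moving beam, i.e. the beam intensity integrated along ``y``.

Figures of merit of a sheet (the axial-resolution / field-of-view /
optical-sectioning triangle):

* **thickness** — FWHM of the central lobe of ``I(x₀, z)`` at the focal
  plane; bounds the achievable axial resolution.
* **length** — FWHM along ``x`` of the beam's on-axis intensity; the usable
  field of view per tile (the classical Bessel/Gaussian beam length).
* **uniform range** — contiguous ``x`` range over which the central-lobe
  FWHM stays within √2 of its minimum (a Rayleigh-style stability span).
* **confinement** — fraction of the illumination at the focal plane that
  falls within the detection depth of focus ``n·λ_em/NA_det²``; controls
  out-of-focus background and photodamage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .slm_patterns import (
    AnnulusSpec,
    PhaseMapBinary,
    PhaseMapContinuous,
    PupilCalibration,
    SlmGrid,
)

__all__ = [
    "GridSpec",
    "OpticalConfig",
    "SlitSpec",
    "ComplexField2D",
    "FocalVolume",
    "SheetProfile",
    "SheetMetrics",
    "Psf3D",
    "OtfSupport",
    "pupil_grid",
    "pupil_field",
    "annular_pupil_field",
    "to_image_plane",
    "to_pupil_plane",
    "apply_slit",
    "remove_carrier",
    "propagate_to_focus",
    "propagate_slm_map",
    "sweep_sheet",
    "dither_sheet",
    "beam_axial_intensity",
    "interp_fwhm",
    "central_lobe_fwhm",
    "sheet_metrics",
    "detection_psf",
    "system_psf",
    "otf_support",
]


def _cfft2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a), norm="ortho"))


def _icfft2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a), norm="ortho"))


@dataclass(frozen=True)
class GridSpec:
    """Sampling of the focal region.

    ``step_transverse`` is the (y, z) pixel in um; the image-space window is
    ``n_transverse·step_transverse`` wide and fixes the pupil NA sampling
    through the FFT relation ``Δna = λ/(N·step)``.  ``step_axial``/``n_axial``
    sample the propagation axis x.
    """

    n_transverse: int = 512
    step_transverse: float = 0.135
    n_axial: int = 121
    step_axial: float = 0.25

    def __post_init__(self) -> None:
        if self.n_transverse < 16 or self.n_axial < 1:
            raise ValueError("grid too small")
        if self.step_transverse <= 0 or self.step_axial <= 0:
            raise ValueError("grid steps must be positive")

    def transverse_coords(self) -> np.ndarray:
        return (np.arange(self.n_transverse) - self.n_transverse // 2) * self.step_transverse

    def axial_coords(self) -> np.ndarray:
        return (np.arange(self.n_axial) - self.n_axial // 2) * self.step_axial


@dataclass(frozen=True)
class OpticalConfig:
    """Wavelengths, medium, detection NA and sampling for a simulation run."""

    wavelength_exc: float = 0.488  # um
    wavelength_em: float = 0.510  # um (GFP); 0.590 for mCherry
    medium_index: float = 1.33  # water
    na_detection: float = 0.8
    na_max_sim: float = 0.55  # highest excitation NA the pupil must carry
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.na_detection > self.medium_index:
            raise ValueError("detection NA cannot exceed the medium index")
        crit = min(self.wavelength_exc, self.wavelength_em) / (
            4.0 * max(self.na_max_sim, self.na_detection)
        )
        if self.grid.step_transverse > crit:
            raise ValueError(
                f"transverse step {self.grid.step_transverse} um undersamples "
                f"NA {max(self.na_max_sim, self.na_detection)}; need <= {crit:.4f} um"
            )

    @property
    def depth_of_focus(self) -> float:
        """Detection depth of focus n·λ_em/NA² in um."""
        return self.medium_index * self.wavelength_em / self.na_detection**2


@dataclass(frozen=True)
class SlitSpec:
    """Rectangular passband of the optical slit in the image-conjugate plane.

    The slit passes ``|y − center_um| <= width_um/2`` along the dither axis,
    blocking the abandon-grating orders and the conjugate order of binarized
    designs.
    """

    center_um: float = 0.0
    width_um: float = 30.0

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("slit passband must have positive width")


@dataclass(frozen=True)
class ComplexField2D:
    """Complex scalar amplitude on a transverse grid at a named plane."""

    values: np.ndarray
    plane: str  # "pupil" | "image"
    wavelength: float
    step_um: float  # image-plane pixel; pupil NA step is lam/(N*step_um)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("field must be a finite 2D complex array")
        object.__setattr__(self, "values", v)

    @property
    def na_step(self) -> float:
        return self.wavelength / (self.values.shape[0] * self.step_um)

    def power(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass(frozen=True)
class FocalVolume:
    """3D intensity I[x, y, z] of a beam around the focus (axes in um)."""

    intensity: np.ndarray  # shape (nx, ny, nz)
    x_coords: np.ndarray
    step_transverse: float

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")


@dataclass(frozen=True)
class SheetProfile:
    """Swept/dithered sheet intensity I[x, z] (y integrated out)."""

    intensity: np.ndarray  # shape (nx, nz)
    x_coords: np.ndarray
    z_coords: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    def z_profile(self, x_um: float = 0.0) -> np.ndarray:
        """Interpolated I(z) at propagation position ``x_um``."""
        i = np.clip(np.searchsorted(self.x_coords, x_um), 1, len(self.x_coords) - 1)
        x0, x1 = self.x_coords[i - 1], self.x_coords[i]
        w = 0.0 if x1 == x0 else (x_um - x0) / (x1 - x0)
        return (1 - w) * self.intensity[i - 1] + w * self.intensity[i]


@dataclass(frozen=True)
class SheetMetrics:
    """Thickness / length / confinement triple plus the √2-stability span."""

    thickness: float  # um, central-lobe FWHM at focus
    length: float  # um, axial FWHM of the on-axis beam intensity
    confinement: float  # fraction of focal-plane illumination inside the DOF
    uniform_range: tuple[float, float]  # x range where lobe FWHM <= sqrt(2)*min

    @property
    def uniform_length(self) -> float:
        return self.uniform_range[1] - self.uniform_range[0]


@dataclass(frozen=True)
class Psf3D:
    """3D intensity PSF, array order (z, y, x), voxel sizes in um."""

    data: np.ndarray
    voxel: tuple[float, float, float]  # (dz, dy, dx)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or np.any(d < 0):
            raise ValueError("PSF must be a nonnegative 3D array")
        total = d.sum()
        if total <= 0:
            raise ValueError("PSF must have positive total intensity")
        object.__setattr__(self, "data", d / total)


@dataclass(frozen=True)
class OtfSupport:
    """Boolean frequency-support mask of a PSF (same array order as the PSF)."""

    mask: np.ndarray
    voxel: tuple[float, float, float]


# ---------------------------------------------------------------------------
# pupil construction and plane-to-plane transport


def pupil_grid(cfg: OpticalConfig, wavelength: float) -> tuple[SlmGrid, PupilCalibration]:
    """SLM-style grid + calibration matching the simulation's pupil sampling.

    Phase maps designed on this grid drop straight onto the FFT pupil grid
    with one NA unit per ``λ/(N·step)``.
    """
    n = cfg.grid.n_transverse
    dna = wavelength / (n * cfg.grid.step_transverse)
    return SlmGrid(n_cols=n, n_rows=n, pixel_pitch=1.0), PupilCalibration(na_per_px=dna)


def pupil_field(
    phase_map: PhaseMapBinary | PhaseMapContinuous | np.ndarray,
    cfg: OpticalConfig,
    wavelength: float | None = None,
    amplitude: np.ndarray | None = None,
) -> ComplexField2D:
    """Unit-amplitude pupil field ``e^{iφ}`` from an SLM phase map.

    The incident beam is taken as uniform over the modulator; shaping is done
    entirely by the retain/abandon phase pattern, as on the real device.
    """
    lam = cfg.wavelength_exc if wavelength is None else wavelength
    phase = phase_map.values if hasattr(phase_map, "values") else np.asarray(phase_map)
    if phase.shape[0] != phase.shape[1]:
        raise ValueError("simulation pupils must be square")
    values = np.exp(1j * phase)
    # circular pupil stop: the relay aperture clips the square SLM at the
    # inscribed circle, which also keeps the field inside the Nyquist band
    n = phase.shape[0]
    dna = lam / (n * cfg.grid.step_transverse)
    na_lin = (np.arange(n) - n // 2) * dna
    rho = np.hypot(na_lin[:, None], na_lin[None, :])
    values = values * (rho <= dna * (n // 2))
    if amplitude is not None:
        values = values * amplitude
    return ComplexField2D(values, "pupil", lam, cfg.grid.step_transverse)


def annular_pupil_field(annulus: AnnulusSpec, cfg: OpticalConfig) -> ComplexField2D:
    """Ideal amplitude-masked annular pupil (the photo-mask reference case)."""
    grid, cal = pupil_grid(cfg, cfg.wavelength_exc)
    na = cal.na_radius(grid)
    mask = (na >= annulus.na_inner) & (na <= annulus.na_outer)
    return ComplexField2D(
        mask.astype(complex), "pupil", cfg.wavelength_exc, cfg.grid.step_transverse
    )


def to_image_plane(pupil: ComplexField2D) -> ComplexField2D:
    if pupil.plane != "pupil":
        raise ValueError(f"expected a pupil-plane field, got {pupil.plane!r}")
    return replace(pupil, values=_cfft2(pupil.values), plane="image")


def to_pupil_plane(image: ComplexField2D) -> ComplexField2D:
    if image.plane != "image":
        raise ValueError(f"expected an image-plane field, got {image.plane!r}")
    return replace(image, values=_icfft2(image.values), plane="pupil")


def apply_slit(image_field: ComplexField2D, slit: SlitSpec) -> ComplexField2D:
    """Zero the image-conjugate field outside the slit passband (y axis)."""
    if image_field.plane != "image":
        raise ValueError("the optical slit sits in an image-conjugate plane")
    n = image_field.values.shape[0]
    y = (np.arange(n) - n // 2) * image_field.step_um
    keep = np.abs(y - slit.center_um) <= slit.width_um / 2.0
    if not keep.any():
        raise ValueError("slit passband lies outside the simulated window")
    return replace(image_field, values=image_field.values * keep[:, None])


def remove_carrier(
    pupil: ComplexField2D, offset_um: float, axis: int = 0
) -> ComplexField2D:
    """Undo a lateral carrier tilt (the galvo recentring after the slit)."""
    if pupil.plane != "pupil":
        raise ValueError("carrier removal acts on the pupil field")
    n = pupil.values.shape[0]
    na_lin = (np.arange(n) - n // 2) * pupil.na_step
    ramp = np.exp(-2j * math.pi / pupil.wavelength * offset_um * na_lin)
    values = pupil.values * (ramp[:, None] if axis == 0 else ramp[None, :])
    return replace(pupil, values=values)


def propagate_to_focus(
    pupil: ComplexField2D,
    cfg: OpticalConfig,
    x_coords: np.ndarray | None = None,
) -> FocalVolume:
    """Angular-spectrum propagation of a pupil field to the focal volume.

    Power in the propagating band is conserved plane to plane (the transport
    is a unitary FFT times a pure phase).  Raises if the pupil carries
    significant energy at NA beyond the Nyquist limit of the grid.
    """
    if pupil.plane != "pupil":
        raise ValueError("propagation starts from a pupil-plane field")
    lam = pupil.wavelength
    n_med = cfg.medium_index
    n = pupil.values.shape[0]
    na_lin = (np.arange(n) - n // 2) * pupil.na_step
    na_y, na_z = np.meshgrid(na_lin, na_lin, indexing="ij")
    rho2 = na_y**2 + na_z**2
    propagating = rho2 < n_med**2
    na_nyquist = lam / (2.0 * cfg.grid.step_transverse)
    band = pupil.values * propagating
    if na_nyquist < n_med:
        # two-pixel guard band: the pupil stop sits exactly at Nyquist and
        # slit convolution smears a boundary ring that carries no information
        outside = np.abs(band[np.sqrt(rho2) > na_nyquist + 2 * pupil.na_step]) ** 2
        if outside.sum() > 1e-3 * pupil.power():
            raise ValueError(
                f"pupil undersampled: energy beyond NA {na_nyquist:.3f}; "
                f"reduce step_transverse below "
                f"{lam / (2 * math.sqrt(rho2[np.abs(pupil.values)>0].max())):.4f} um"
            )
    kx = (2 * math.pi / lam) * np.sqrt(np.clip(n_med**2 - rho2, 0.0, None))
    if x_coords is None:
        x_coords = cfg.grid.axial_coords()
    x_coords = np.asarray(x_coords, dtype=float)
    intensity = np.empty((x_coords.size, n, n))
    for i, x in enumerate(x_coords):
        e = _icfft2(band * np.exp(1j * kx * x))
        intensity[i] = np.abs(e) ** 2
    return FocalVolume(intensity, x_coords, cfg.grid.step_transverse)


def propagate_coherent_maps(
    image_map: PhaseMapBinary,
    pupil_map: PhaseMapBinary,
    cfg: OpticalConfig,
    slit: SlitSpec | None = None,
    illumination_halfwidth_um: float = 20.0,
    x_coords: np.ndarray | None = None,
) -> tuple[ComplexField2D, FocalVolume]:
    """Two-SLM (lattice) excitation path: image-plane SLM → pupil SLM → slit.

    The image-plane modulator is illuminated by a finite Gaussian stripe
    along the dither axis (a cylindrical-lens beam in hardware; numerically
    it also keeps abandoned orders from wrapping through the periodic
    window).  The pupil-plane map applies the annulus/abandon-grating
    filter, the slit blocks the diverted light, and the excitation
    objective's aperture (``cfg.na_max_sim``) clips what remains.

    Returns the filtered pupil field (for e.g. concentration checks) and
    the propagated focal volume.
    """
    n = image_map.values.shape[0]
    if image_map.values.shape != pupil_map.values.shape or n != cfg.grid.n_transverse:
        raise ValueError("image and pupil maps must match the simulation grid")
    step = cfg.grid.step_transverse
    y = (np.arange(n) - n // 2) * step
    stripe = np.exp(-(y[:, None] ** 2) / (2 * illumination_halfwidth_um**2))
    field = ComplexField2D(
        np.exp(1j * image_map.values) * stripe, "image", cfg.wavelength_exc, step
    )
    pup = to_pupil_plane(field)
    pup = replace(pup, values=pup.values * np.exp(1j * pupil_map.values))
    if slit is not None:
        pup = to_pupil_plane(apply_slit(to_image_plane(pup), slit))
    # excitation-objective pupil stop
    na_lin = (np.arange(n) - n // 2) * pup.na_step
    rho = np.hypot(na_lin[:, None], na_lin[None, :])
    pup = replace(pup, values=pup.values * (rho <= cfg.na_max_sim))
    return pup, propagate_to_focus(pup, cfg, x_coords)


def propagate_slm_map(
    slm_map: PhaseMapBinary,
    cfg: OpticalConfig,
    slit: SlitSpec | None = None,
    carrier_offset_um: float = 0.0,
    x_coords: np.ndarray | None = None,
) -> FocalVolume:
    """Full excitation path: SLM pupil → slit plane → focal volume.

    The binary map is illuminated uniformly, Fourier-transformed to the
    image-conjugate slit plane where the passband is applied, transformed
    back, recentred (carrier removal) and propagated around the focus.
    """
    field = pupil_field(slm_map, cfg)
    if slit is not None:
        field = to_pupil_plane(apply_slit(to_image_plane(field), slit))
    if carrier_offset_um:
        field = remove_carrier(field, carrier_offset_um)
    return propagate_to_focus(field, cfg, x_coords)


# ---------------------------------------------------------------------------
# sheets and metrics


def sweep_sheet(vol: FocalVolume) -> SheetProfile:
    """Incoherent time average of a swept beam: integrate intensity over y."""
    n = vol.intensity.shape[2]
    z = (np.arange(n) - n // 2) * vol.step_transverse
    return SheetProfile(vol.intensity.sum(axis=1) * vol.step_transverse, vol.x_coords, z)


def dither_sheet(vol: FocalVolume) -> SheetProfile:
    """Dithered beam-array sheet; identical time average as a full sweep."""
    return sweep_sheet(vol)


def beam_axial_intensity(vol: FocalVolume) -> np.ndarray:
    """On-axis beam intensity I(x, y=0, z=0)."""
    _, ny, nz = vol.intensity.shape
    return vol.intensity[:, ny // 2, nz // 2].copy()


def interp_fwhm(coords: np.ndarray, values: np.ndarray) -> float:
    """FWHM of a single-peaked sampled curve by linear interpolation."""
    values = np.asarray(values, dtype=float)
    j = int(np.argmax(values))
    half = values[j] / 2.0
    lo = np.where(values[: j + 1] <= half)[0]
    hi = np.where(values[j:] <= half)[0]
    if lo.size == 0 or hi.size == 0:
        return math.inf
    a = lo[-1]
    b = j + hi[0]
    xl = np.interp(half, [values[a], values[a + 1]], [coords[a], coords[a + 1]])
    xr = np.interp(half, [values[b], values[b - 1]], [coords[b], coords[b - 1]])
    return float(xr - xl)


def central_lobe_fwhm(z: np.ndarray, profile: np.ndarray, max_walk: int = 30) -> float:
    """FWHM of the lobe containing z = 0, by half-max crossings of that lobe.

    Walks uphill from z = 0 to the local peak (inf if none within
    ``max_walk`` samples), then walks down each flank; returns inf when a
    flank rises again before reaching half maximum (lobe merged into
    side-lobe structure — no usable central lobe).
    """
    profile = np.asarray(profile, dtype=float)
    j = int(np.argmin(np.abs(z)))
    steps = 0
    while 0 < j < len(profile) - 1 and (
        profile[j + 1] > profile[j] or profile[j - 1] > profile[j]
    ):
        j += 1 if profile[j + 1] > profile[j - 1] else -1
        steps += 1
        if steps > max_walk:
            return math.inf
    half = profile[j] / 2.0
    right = j
    while right < len(profile) - 1 and profile[right + 1] < profile[right]:
        right += 1
        if profile[right] <= half:
            break
    left = j
    while left > 0 and profile[left - 1] < profile[left]:
        left -= 1
        if profile[left] <= half:
            break
    if profile[right] > half or profile[left] > half:
        return math.inf
    zr = np.interp(half, [profile[right], profile[right - 1]], [z[right], z[right - 1]])
    zl = np.interp(half, [profile[left], profile[left + 1]], [z[left], z[left + 1]])
    return float(zr - zl)


def sheet_metrics(
    profile: SheetProfile,
    cfg: OpticalConfig,
    axial_intensity: np.ndarray | None = None,
    depth_of_focus: float | None = None,
) -> SheetMetrics:
    """Thickness, length, confinement and stability span of a sheet profile.

    ``axial_intensity`` is the beam's on-axis intensity sampled on
    ``profile.x_coords`` (see :func:`beam_axial_intensity`); when omitted the
    sheet's own ``I(x, z≈0)`` is used for the length, which overestimates the
    beam length slightly because the swept side lobes decay more slowly.
    """
    z = profile.z_coords
    x = profile.x_coords
    iz0 = int(np.argmin(np.abs(z)))
    x_peak = int(np.argmax(profile.intensity[:, iz0]))
    focal = profile.intensity[x_peak]
    thickness = central_lobe_fwhm(z, focal)
    if not math.isfinite(thickness):
        raise ValueError("profile has no central lobe at the focal plane")
    widths = np.array([central_lobe_fwhm(z, profile.intensity[i]) for i in range(len(x))])
    w_min = np.nanmin(widths[np.isfinite(widths)])
    limit = math.sqrt(2.0) * w_min
    ok = widths <= limit
    a = b = int(np.nanargmin(np.where(np.isfinite(widths), widths, np.nan)))
    while a > 0 and ok[a - 1]:
        a -= 1
    while b < len(x) - 1 and ok[b + 1]:
        b += 1
    # interpolate the crossing of the sqrt(2) limit on both flanks
    x_lo = x[a]
    if a > 0 and math.isfinite(widths[a - 1]):
        x_lo = float(np.interp(limit, [widths[a], widths[a - 1]], [x[a], x[a - 1]]))
    x_hi = x[b]
    if b < len(x) - 1 and math.isfinite(widths[b + 1]):
        x_hi = float(np.interp(limit, [widths[b], widths[b + 1]], [x[b], x[b + 1]]))
    axial = profile.intensity[:, iz0] if axial_intensity is None else np.asarray(axial_intensity)
    length = interp_fwhm(x, axial)
    dof = cfg.depth_of_focus if depth_of_focus is None else depth_of_focus
    inside = np.abs(z) <= dof
    confinement = float(focal[inside].sum() / focal.sum())
    return SheetMetrics(thickness, length, confinement, (x_lo, x_hi))


# ---------------------------------------------------------------------------
# point-spread functions


def detection_psf(
    cfg: OpticalConfig,
    shape: tuple[int, int, int] = (61, 128, 128),
    voxel: tuple[float, float, float] | None = None,
) -> Psf3D:
    """Scalar widefield detection PSF at λ_em for the detection objective.

    ``shape`` is (nz, ny, nx) with z the detection (defocus) axis; ``voxel``
    defaults to (grid.step_axial/…) — explicitly: (0.1, step, step) must be
    given by callers needing a specific camera grid.  Normalized to unit sum.
    """
    if voxel is None:
        voxel = (
            cfg.grid.step_transverse,
            cfg.grid.step_transverse,
            cfg.grid.step_transverse,
        )
    nz, ny, nx = shape
    if ny != nx:
        raise ValueError("transverse PSF support must be square")
    dz, dy, dx = voxel
    if dy != dx:
        raise ValueError("transverse PSF voxel must be isotropic")
    lam = cfg.wavelength_em
    crit = lam / (4.0 * cfg.na_detection)
    if dx > crit:
        raise ValueError(f"PSF voxel {dx} um undersamples NA {cfg.na_detection}; need <= {crit:.4f}")
    n_med = cfg.medium_index
    dna = lam / (nx * dx)
    na_lin = (np.arange(nx) - nx // 2) * dna
    na_a, na_b = np.meshgrid(na_lin, na_lin, indexing="ij")
    rho2 = na_a**2 + na_b**2
    pupil = (rho2 <= cfg.na_detection**2).astype(complex)
    kz = (2 * math.pi / lam) * np.sqrt(np.clip(n_med**2 - rho2, 0.0, None))
    z_coords = (np.arange(nz) - nz // 2) * dz
    data = np.empty(shape)
    for i, zc in enumerate(z_coords):
        e = _icfft2(pupil * np.exp(1j * kz * zc))
        data[i] = np.abs(e) ** 2
    return Psf3D(data, voxel)


def system_psf(
    sheet: SheetProfile,
    det: Psf3D,
    tile_center_x: float = 0.0,
) -> Psf3D:
    """Overall PSF of sheet illumination plus widefield detection.

    The detection PSF is weighted along z by the sheet's z-profile at the
    tile centre (sample-space product of excitation and detection), then
    renormalized.  An infinitely thick sheet returns the detection PSF.
    """
    nz = det.data.shape[0]
    dz = det.voxel[0]
    z = (np.arange(nz) - nz // 2) * dz
    prof = sheet.z_profile(tile_center_x)
    weight = np.interp(z, sheet.z_coords, prof, left=0.0, right=0.0)
    if weight.max() <= 0:
        raise ValueError("sheet profile does not overlap the PSF z support")
    data = det.data * (weight / weight.max())[:, None, None]
    return Psf3D(data, det.voxel)


def otf_support(psf: Psf3D, floor: float = 1e-3) -> OtfSupport:
    """Frequencies where the OTF magnitude exceeds ``floor`` × its maximum.

    The mask is symmetrized under frequency negation so that filtering with
    it keeps images real.
    """
    if not 0 < floor < 1:
        raise ValueError("floor must lie in (0, 1)")
    otf = np.abs(np.fft.fftn(psf.data))
    mask = otf >= floor * otf.max()
    flipped = mask[
        np.ix_(*[(-np.arange(s)) % s for s in mask.shape])
    ]  # index negation mod n
    return OtfSupport(mask | flipped, psf.voxel)
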