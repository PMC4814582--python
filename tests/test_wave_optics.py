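"""Propagation oracles, sheet metrics, PSFs and OTF support."""

import math

import numpy as np
import pytest
from scipy.special import j0

from tilesheet import (
    AnnulusSpec,
    SlitSpec,
    TilingShift,
    annular_pupil_field,
    apply_slit,
    beam_axial_intensity,
    bessel_tiled_map,
    dammann_tiled_map,
    design_dammann,
    detection_psf,
    otf_support,
    propagate_slm_map,
    propagate_to_focus,
    pupil_field,
    pupil_grid,
    sheet_metrics,
    sweep_sheet,
    system_psf,
)
from tilesheet.slm_patterns import (
    PhaseMapBinary,
    abandon_grating,
    compose_retain_abandon,
)
from tilesheet.wave_optics import (
    SheetProfile,
    central_lobe_fwhm,
    interp_fwhm,
    to_image_plane,
    to_pupil_plane,
)


class TestPropagation:
    def test_uniform_disc_matches_airy(self, cfg_fast):
        """Focal profile of a filled 0.35 NA pupil: FWHM ≈ 0.51 λ/NA."""
        vol = propagate_to_focus(
            annular_pupil_field(AnnulusSpec(1e-9, 0.35), cfg_fast), cfg_fast, [0.0]
        )
        n = cfg_fast.grid.n_transverse
        r = cfg_fast.grid.transverse_coords()
        prof = vol.intensity[0, n // 2]
        fwhm = interp_fwhm(r, prof)
        assert fwhm == pytest.approx(0.514 * cfg_fast.wavelength_exc / 0.35, rel=0.03)

    def test_thin_annulus_matches_bessel_j0(self, cfg_fast):
        """Thin ring pupil gives J0²(k·na·r) with ≤3% RMS on the central lobe."""
        vol = propagate_to_focus(
            annular_pupil_field(AnnulusSpec(0.34, 0.35), cfg_fast), cfg_fast, [0.0]
        )
        n = cfg_fast.grid.n_transverse
        r = cfg_fast.grid.transverse_coords()
        prof = vol.intensity[0, n // 2]
        prof = prof / prof.max()
        k = 2 * math.pi / cfg_fast.wavelength_exc
        theory = j0(k * 0.345 * np.abs(r)) ** 2
        lobe = np.abs(r) < 2.405 / (k * 0.345)
        rms = np.sqrt(np.mean((prof[lobe] - theory[lobe]) ** 2))
        assert rms <= 0.03

    def test_zero_field_gives_zero_volume(self, cfg_fast):
        field = annular_pupil_field(AnnulusSpec(0.14, 0.35), cfg_fast)
        zero = pupil_field(np.zeros(field.values.shape), cfg_fast, amplitude=np.zeros(field.values.shape))
        vol = propagate_to_focus(zero, cfg_fast, [0.0, 5.0])
        assert not vol.intensity.any()

    def test_energy_conserved_across_planes(self, cfg_fast, bessel_annulus):
        """Propagating-band power constant along x to within 0.5%."""
        vol = propagate_to_focus(
            annular_pupil_field(bessel_annulus, cfg_fast), cfg_fast, [-10, -3, 0, 3, 10]
        )
        powers = vol.intensity.sum(axis=(1, 2))
        assert powers.std() / powers.mean() < 0.005


class TestSlit:
    def test_full_plane_passband_is_identity(self, cfg_fast, bessel_annulus):
        f = to_image_plane(annular_pupil_field(bessel_annulus, cfg_fast))
        out = apply_slit(f, SlitSpec(0.0, 1e6))
        np.testing.assert_array_equal(out.values, f.values)

    def test_abandon_grating_blocked(self, cfg_fast):
        """An all-abandon map keeps ≤1% of its power inside the slit."""
        grid, _ = pupil_grid(cfg_fast, cfg_fast.wavelength_exc)
        m = compose_retain_abandon(
            np.zeros(grid.shape, bool),
            PhaseMapBinary(np.zeros(grid.shape), grid),
            abandon_grating(grid),
        )
        img = to_image_plane(pupil_field(m, cfg_fast))
        passed = apply_slit(img, SlitSpec(0.0, 12.0))
        assert passed.power() <= 0.01 * img.power()

    def test_binary_defocus_single_order_survives(self, cfg_fast, bessel_annulus):
        """With a carrier tilt, the slit keeps the +d order and kills −d."""
        grid, cal = pupil_grid(cfg_fast, cfg_fast.wavelength_exc)
        m = bessel_tiled_map(
            TilingShift(6.0), bessel_annulus, grid, cal, cfg_fast.wavelength_exc,
            carrier_offset_um=10.0,
        )
        vol = propagate_slm_map(
            m, cfg_fast, slit=SlitSpec(10.0, 12.0), carrier_offset_um=10.0,
            x_coords=np.arange(-10.0, 10.5, 0.5),
        )
        ax = beam_axial_intensity(vol)
        xs = vol.x_coords
        i_plus = ax[np.argmin(np.abs(xs - 6.0))]
        i_minus = ax[np.argmin(np.abs(xs + 6.0))]
        assert abs(xs[np.argmax(ax)] - 6.0) <= 1.0
        assert i_plus > 20 * i_minus

    def test_empty_passband_rejected(self, cfg_fast, bessel_annulus):
        f = to_image_plane(annular_pupil_field(bessel_annulus, cfg_fast))
        with pytest.raises(ValueError):
            apply_slit(f, SlitSpec(1e5, 1.0))


@pytest.fixture(scope="module")
def cfg_array():
    """Wide window → fine NA sampling: many grating periods per annulus."""
    from tilesheet import GridSpec, OpticalConfig

    return OpticalConfig(na_detection=0.35, na_max_sim=0.35,
                         grid=GridSpec(512, 0.3, 3, 0.5))


class TestSheets:
    def test_y_invariant_volume_profile_equals_slice(self, cfg_fast):
        from tilesheet.wave_optics import FocalVolume

        intensity = np.tile(np.random.default_rng(0).uniform(
            0.0, 1.0, (3, 1, 32)), (1, 16, 1))
        vol = FocalVolume(intensity, np.array([-1.0, 0.0, 1.0]), 0.2)
        sheet = sweep_sheet(vol)
        expected = intensity[:, 0, :] * 16 * 0.2
        np.testing.assert_allclose(sheet.intensity, expected, rtol=1e-12)

    def test_single_bessel_sheet_thickness(self, cfg_full, bessel_annulus):
        """NA 0.14/0.35 annulus at 488 nm: swept-sheet waist ≈ 0.7 um."""
        vol = propagate_to_focus(
            annular_pupil_field(bessel_annulus, cfg_full), cfg_full, [0.0]
        )
        prof = sweep_sheet(vol)
        z = prof.z_coords
        assert central_lobe_fwhm(z, prof.intensity[0]) == pytest.approx(0.7, rel=0.25)

    def test_incoherent_array_sheet_is_sum_of_singles(self, cfg_array, bessel_annulus):
        """Dithered 7-beam incoherent sheet ≈ superposition of displaced
        single-beam sheets (cross terms average out along the sweep)."""
        grid, cal = pupil_grid(cfg_array, cfg_array.wavelength_exc)
        # pixel quantization of the short period costs order uniformity but
        # leaves the foci in place, which is all this comparison needs
        spec = design_dammann(7, period_px=32, max_spread=0.2)
        m = dammann_tiled_map(
            spec, TilingShift(0.0), bessel_annulus, grid, cal,
            cfg_array.wavelength_exc, carrier_offset_um=0.0,
        )
        vol = propagate_slm_map(m, cfg_array, slit=SlitSpec(0.0, 40.0), x_coords=[0.0])
        array_sheet = vol.intensity[0].sum(axis=0)
        single = propagate_to_focus(
            annular_pupil_field(bessel_annulus, cfg_array), cfg_array, [0.0]
        ).intensity[0].sum(axis=0)
        array_sheet = array_sheet / array_sheet.max()
        single = single / single.max()
        n = cfg_array.grid.n_transverse
        center = slice(n // 2 - 40, n // 2 + 41)
        rms = np.sqrt(np.mean((array_sheet[center] - single[center]) ** 2))
        assert rms <= 0.1

    def test_seven_beam_array_has_seven_foci(self, cfg_array, bessel_annulus):
        """The Dammann map (behind the slit) produces 7 foci on the dither axis."""
        grid, cal = pupil_grid(cfg_array, cfg_array.wavelength_exc)
        spec = design_dammann(7, period_px=32, max_spread=0.2)
        m = dammann_tiled_map(
            spec, TilingShift(0.0), bessel_annulus, grid, cal, cfg_array.wavelength_exc,
        )
        vol = propagate_slm_map(m, cfg_array, slit=SlitSpec(0.0, 40.0), x_coords=[0.0])
        n = cfg_array.grid.n_transverse
        line = vol.intensity[0, :, n // 2]
        # count peaks above half the tallest focus
        peaks = [
            i for i in range(1, n - 1)
            if line[i] > line[i - 1] and line[i] >= line[i + 1]
            and line[i] > 0.5 * line.max()
        ]
        assert len(peaks) == 7


class TestSheetMetrics:
    def test_gaussian_profile_thickness_closed_form(self, cfg_fast):
        sigma = 0.5
        z = np.linspace(-5, 5, 401)
        x = np.linspace(-10, 10, 41)
        intensity = np.exp(-(z[None, :] ** 2) / (2 * sigma**2)) * np.exp(
            -(x[:, None] ** 2) / 50.0
        )
        prof = SheetProfile(intensity, x, z)
        m = sheet_metrics(prof, cfg_fast)
        assert m.thickness == pytest.approx(2.355 * sigma, rel=0.01)

    def test_sheet_inside_dof_has_full_confinement(self, cfg_fast):
        z = np.linspace(-5, 5, 401)
        x = np.linspace(-10, 10, 11)
        narrow = np.exp(-(z[None, :] ** 2) / (2 * 0.1**2)) * np.ones((11, 1))
        prof = SheetProfile(narrow, x, z)
        m = sheet_metrics(prof, cfg_fast, depth_of_focus=2.0)
        assert m.confinement == pytest.approx(1.0, abs=1e-6)

    def test_profile_without_central_lobe_rejected(self, cfg_fast):
        z = np.linspace(-5, 5, 401)
        x = np.linspace(-10, 10, 11)
        ring = np.exp(-((np.abs(z[None, :]) - 3.0) ** 2) / 0.1) * np.ones((11, 1))
        with pytest.raises(ValueError, match="central lobe"):
            sheet_metrics(SheetProfile(ring, x, z), cfg_fast)

    def test_thickness_scaling_law(self, cfg_fast):
        """Scaling the annulus by α scales the waist by 1/α (within 5%)."""
        thicknesses = {}
        for alpha in (1.0, 1.4):
            ann = AnnulusSpec(0.14 * alpha, 0.35 * alpha)
            vol = propagate_to_focus(
                annular_pupil_field(ann, cfg_fast), cfg_fast, [0.0]
            )
            prof = sweep_sheet(vol)
            thicknesses[alpha] = central_lobe_fwhm(prof.z_coords, prof.intensity[0])
        assert thicknesses[1.0] / thicknesses[1.4] == pytest.approx(1.4, rel=0.05)

    def test_tradeoff_thinner_means_shorter_and_more_confined(self, cfg_fast):
        """Across an annulus family: smaller thickness ↔ smaller length and
        larger confinement — the axial-resolution/FOV/sectioning tradeoff."""
        rows = []
        for alpha in (0.6, 1.0, 1.4):
            ann = AnnulusSpec(0.14 * alpha, 0.35 * alpha)
            vol = propagate_to_focus(
                annular_pupil_field(ann, cfg_fast), cfg_fast,
                np.arange(-30.0, 30.5, 1.0),
            )
            m = sheet_metrics(
                sweep_sheet(vol), cfg_fast, axial_intensity=beam_axial_intensity(vol)
            )
            rows.append((m.thickness, m.length, m.confinement))
        thick, length, conf = zip(*rows)
        assert thick[0] > thick[1] > thick[2]
        assert length[0] > length[1] > length[2]
        assert conf[0] < conf[1] < conf[2]


class TestPsfs:
    def test_detection_psf_lateral_fwhm(self, cfg_fast):
        """0.8 NA water objective at 510 nm: lateral FWHM ≈ 320 nm."""
        psf = detection_psf(cfg_fast, shape=(3, 257, 257), voxel=(0.1, 0.05, 0.05))
        mid = psf.data[1]
        r = (np.arange(257) - 128) * 0.05
        fwhm = interp_fwhm(r, mid[128])
        assert fwhm == pytest.approx(0.32, rel=0.1)

    def test_detection_psf_axial_fwhm_near_closed_form(self, cfg_fast):
        """Axial FWHM ≈ 1.77 n λ/NA² within 10% (scalar approximation)."""
        psf = detection_psf(cfg_fast, shape=(81, 129, 129), voxel=(0.1, 0.15, 0.15))
        z = (np.arange(81) - 40) * 0.1
        fwhm = interp_fwhm(z, psf.data[:, 64, 64])
        expected = 1.77 * 1.33 * 0.510 / 0.8**2
        assert fwhm == pytest.approx(expected, rel=0.1)

    def test_detection_psf_inversion_symmetric(self, cfg_fast):
        """Aberration-free pupil: PSF symmetric under (x,y) → (−x,−y)."""
        psf = detection_psf(cfg_fast, shape=(5, 65, 65), voxel=(0.2, 0.15, 0.15))
        mid = psf.data[2]  # odd grid: exact inversion centre
        np.testing.assert_allclose(mid, mid[::-1, ::-1], atol=1e-12 * psf.data.max())

    def test_system_psf_with_thick_sheet_is_detection_psf(self, cfg_fast):
        det = detection_psf(cfg_fast, shape=(41, 65, 65), voxel=(0.15, 0.15, 0.15))
        z = np.linspace(-50, 50, 101)
        x = np.linspace(-10, 10, 11)
        flat = SheetProfile(np.ones((11, 101)), x, z)
        sys = system_psf(flat, det)
        np.testing.assert_allclose(sys.data, det.data, rtol=1e-12)

    def test_system_axial_fwhm_gaussian_product(self, cfg_fast):
        """0.7 um sheet × detection: axial FWHM ≈ harmonic combination."""
        det = detection_psf(cfg_fast, shape=(81, 65, 65), voxel=(0.05, 0.15, 0.15))
        zc = (np.arange(81) - 40) * 0.05
        det_axial = interp_fwhm(zc, det.data[:, 32, 32])
        sig = 0.7 / 2.355
        z = np.linspace(-10, 10, 801)
        x = np.linspace(-10, 10, 11)
        sheet = SheetProfile(
            np.tile(np.exp(-(z**2) / (2 * sig**2)), (11, 1)), x, z
        )
        sys = system_psf(sheet, det)
        measured = interp_fwhm(zc, sys.data[:, 32, 32])
        expected = (0.7**-2 + det_axial**-2) ** -0.5
        assert measured == pytest.approx(expected, rel=0.1)

    def test_thinner_sheet_never_broadens_system_psf(self, cfg_fast):
        det = detection_psf(cfg_fast, shape=(41, 65, 65), voxel=(0.1, 0.15, 0.15))
        zc = (np.arange(41) - 20) * 0.1
        z = np.linspace(-10, 10, 801)
        x = np.linspace(-10, 10, 3)
        widths = []
        for fwhm_sheet in (2.0, 1.0, 0.5):
            sig = fwhm_sheet / 2.355
            sheet = SheetProfile(np.tile(np.exp(-(z**2) / (2 * sig**2)), (3, 1)), x, z)
            widths.append(interp_fwhm(zc, system_psf(sheet, det).data[:, 32, 32]))
        assert widths[0] >= widths[1] >= widths[2]


class TestOtfSupport:
    def test_delta_psf_full_support(self):
        from tilesheet.wave_optics import Psf3D

        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        sup = otf_support(Psf3D(data, (0.1, 0.1, 0.1)), floor=0.5)
        assert sup.mask.all()

    def test_support_grows_as_floor_decreases(self, cfg_fast):
        psf = detection_psf(cfg_fast, shape=(21, 65, 65), voxel=(0.2, 0.15, 0.15))
        sizes = [otf_support(psf, floor=f).mask.sum() for f in (0.3, 0.03, 0.003)]
        assert sizes[0] < sizes[1] < sizes[2]

    def test_widefield_lateral_cutoff(self, cfg_fast):
        """Incoherent lateral cutoff ≈ 2 NA/λ within 10%."""
        psf = detection_psf(cfg_fast, shape=(1, 257, 257), voxel=(0.1, 0.05, 0.05))
        sup = otf_support(psf, floor=1e-4)
        freqs = np.fft.fftfreq(257, d=0.05)
        line = sup.mask[0, 0]  # ky = 0 row, kx axis
        kmax = np.abs(freqs[line]).max()
        assert kmax == pytest.approx(2 * 0.8 / 0.510, rel=0.1)

    def test_mask_symmetric_under_negation(self, cfg_fast):
        psf = detection_psf(cfg_fast, shape=(11, 33, 33), voxel=(0.3, 0.15, 0.15))
        sup = otf_support(psf, floor=0.01)
        m = sup.mask
        flipped = m[np.ix_(*[(-np.arange(s)) % s for s in m.shape])]
        np.testing.assert_array_equal(m, flipped)
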