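"""High-level pipelines tying design → propagation → acquisition → recon.

These are the flows a user runs end to end: synthesize a sheet from a beam
recipe, acquire a tiled bead phantom with it, reconstruct, and measure the
resolution actually delivered.  The CLI and the example scripts are thin
wrappers around these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .dammann import design_dammann
from .imaging_sim import (
    CameraModel,
    Phantom,
    TilingPlan,
    bead_phantom,
    plan_tiling,
    simulate_acquisition,
)
from .recon import (
    ReconConfig,
    embed_psf,
    flatfield_correct,
    lowpass_otf,
    measure_bead_fwhm,
    richardson_lucy,
    stitch,
)
from .slm_patterns import TilingShift, bessel_tiled_map, dammann_tiled_map
from .wave_optics import (
    FocalVolume,
    OpticalConfig,
    Psf3D,
    SheetMetrics,
    SheetProfile,
    SlitSpec,
    annular_pupil_field,
    beam_axial_intensity,
    detection_psf,
    otf_support,
    propagate_slm_map,
    propagate_to_focus,
    pupil_grid,
    sheet_metrics,
    sweep_sheet,
    system_psf,
)

__all__ = ["SheetResult", "synthesize_sheet", "BeadRunResult", "bead_resolution_run"]


@dataclass(frozen=True)
class SheetResult:
    volume: FocalVolume
    profile: SheetProfile
    metrics: SheetMetrics


def synthesize_sheet(
    run: RunConfig,
    shift_um: float = 0.0,
    use_slm: bool | None = None,
    x_coords: np.ndarray | None = None,
) -> SheetResult:
    """Build the configured excitation sheet and measure its figures of merit.

    ``use_slm`` selects the binary-SLM path (retain/abandon map, slit,
    carrier) instead of an ideal annular amplitude mask; it defaults to True
    whenever a tiling shift or a beam array demands the SLM.
    """
    cfg = run.optics
    beam = run.beam
    annulus = beam.annulus()
    needs_slm = shift_um != 0.0 or beam.kind == "dammann_array"
    use_slm = needs_slm if use_slm is None else use_slm
    if not use_slm:
        vol = propagate_to_focus(annular_pupil_field(annulus, cfg), cfg, x_coords)
    else:
        grid, cal = pupil_grid(cfg, cfg.wavelength_exc)
        shift = TilingShift(shift_um)
        if beam.kind == "dammann_array" and beam.n_beams > 1:
            spec = design_dammann(beam.n_beams, beam.dammann_period_px)
            slm_map = dammann_tiled_map(
                spec, shift, annulus, grid, cal, cfg.wavelength_exc,
                cfg.medium_index, carrier_offset_um=beam.carrier_offset_um,
            )
        else:
            slm_map = bessel_tiled_map(
                shift, annulus, grid, cal, cfg.wavelength_exc,
                cfg.medium_index, carrier_offset_um=beam.carrier_offset_um,
            )
        slit = SlitSpec(center_um=beam.carrier_offset_um, width_um=run.slit.width_um)
        vol = propagate_slm_map(
            slm_map, cfg, slit=slit, carrier_offset_um=beam.carrier_offset_um,
            x_coords=x_coords,
        )
    profile = sweep_sheet(vol)
    metrics = sheet_metrics(profile, cfg, axial_intensity=beam_axial_intensity(vol))
    return SheetResult(vol, profile, metrics)


@dataclass(frozen=True)
class BeadRunResult:
    phantom: Phantom
    plan: TilingPlan
    stitched: np.ndarray
    deconvolved: np.ndarray
    fwhm_table: pd.DataFrame
    fwhm_table_raw: pd.DataFrame
    psf: Psf3D

    @property
    def median_axial_fwhm_um(self) -> float:
        return float(self.fwhm_table["fwhm_z"].median())

    @property
    def median_lateral_fwhm_um(self) -> float:
        lat = pd.concat([self.fwhm_table["fwhm_x"], self.fwhm_table["fwhm_y"]])
        return float(lat.median())


def bead_resolution_run(run: RunConfig, seed: int | None = None) -> BeadRunResult:
    """Tiled bead acquisition → stitch → RL → OTF low-pass → FWHM table.

    The reconstruction uses the true tile-centre system PSF (sheet z-profile
    × detection PSF), mirroring the practice of measuring one bead PSF per
    imaging configuration, and finishes — like the full analysis chain it
    emulates — by low-pass filtering the deconvolved stack to the system OTF
    support, which removes content beyond the transfer band.
    """
    cfg = run.optics
    ph = run.phantom
    seed = run.seed if seed is None else seed
    sheet = synthesize_sheet(run).profile
    plan = plan_tiling(
        run.tiling.fov_extent_um, run.tiling.sheet_length_um, run.tiling.spacing_um
    )
    phantom = bead_phantom(
        ph.n_objects,
        ph.shape,
        ph.voxel_um,
        min_separation=ph.min_separation_um,
        seed=seed,
    )
    vox = ph.voxel_um
    # odd PSF dims keep scipy's 'same' convolution exactly centred
    nz_psf = min(int(round(6.0 / vox[0])) | 1, (ph.shape[0] - 1) | 1)
    n_xy = min(95, (ph.shape[1] - 1) | 1)
    det = detection_psf(cfg, shape=(nz_psf, n_xy, n_xy), voxel=vox)
    stack = simulate_acquisition(phantom, plan, sheet, det, run.camera)
    corrected = flatfield_correct(stack, sheet, offset=run.camera.offset)
    stitched = stitch(corrected, run.recon)
    psf_sys = system_psf(sheet, det, tile_center_x=0.0)
    deconvolved = richardson_lucy(stitched, psf_sys, run.recon)
    support = otf_support(embed_psf(psf_sys, deconvolved.shape), floor=run.recon.otf_floor)
    deconvolved = np.clip(lowpass_otf(deconvolved, support), 0.0, None)
    table_raw = measure_bead_fwhm(stitched, phantom.centers, vox, expected_fwhm_um=0.5)
    table = measure_bead_fwhm(deconvolved, phantom.centers, vox, expected_fwhm_um=0.5)
    return BeadRunResult(phantom, plan, stitched, deconvolved, table, table_raw, psf_sys)
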