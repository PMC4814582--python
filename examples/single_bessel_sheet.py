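"""Propagate a swept Bessel light sheet and measure its figures of merit.

Builds the annular pupil used for high-resolution imaging (NA 0.14 inner,
0.35 outer, 488 nm excitation in water), propagates it through the focus,
sweeps the beam into a virtual sheet and prints the three quantities that
govern 3D imaging: thickness (axial resolution), length (usable field of
view per tile) and confinement (optical sectioning).
"""

import numpy as np

from tilesheet import (
    AnnulusSpec,
    GridSpec,
    OpticalConfig,
    annular_pupil_field,
    beam_axial_intensity,
    propagate_to_focus,
    sheet_metrics,
    sweep_sheet,
)

cfg = OpticalConfig(grid=GridSpec(n_transverse=512, step_transverse=0.135))
annulus = AnnulusSpec(na_inner=0.14, na_outer=0.35)

x = np.arange(-12.0, 12.1, 0.25)  # positions along the propagation axis, um
volume = propagate_to_focus(annular_pupil_field(annulus, cfg), cfg, x)
profile = sweep_sheet(volume)
metrics = sheet_metrics(profile, cfg, axial_intensity=beam_axial_intensity(volume))

print(f"sheet thickness : {metrics.thickness:.2f} um  (central-lobe FWHM at focus)")
print(f"sheet length    : {metrics.length:.1f} um   (axial FWHM of the beam)")
print(f"confinement     : {metrics.confinement:.2f}     "
      f"(fraction inside the {cfg.depth_of_focus:.2f} um detection DOF)")
# A thin (~0.7 um) sheet resolves subcellular detail axially but stays usable
# for only ~11 um along the beam — hence tiling to cover a whole embryo.
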