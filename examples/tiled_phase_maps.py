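"""Design the binary SLM maps that tile a Bessel sheet to three positions.

The sheet is displaced along its propagation axis purely by changing the
phase map on the pupil-conjugate SLM: a binarized defocus term moves the
focus, the annular retain area shapes the beam, and the high-frequency
grating on the abandon area diverts unused light into the slit.  The three
maps are exported as 8-bit PNGs (0 -> phase 0, 255 -> phase pi) with JSON
sidecars, the format an SLM controller would upload.
"""

from pathlib import Path

from tilesheet import (
    AnnulusSpec,
    PupilCalibration,
    SlmGrid,
    TilingShift,
    bessel_tiled_map,
)
from tilesheet.io import write_phase_map

grid = SlmGrid()  # 1,280 x 1,024 binary SLM
cal = PupilCalibration(na_per_px=0.55 / 512)  # relay puts NA 0.55 at the pupil edge
annulus = AnnulusSpec(0.14, 0.35)

out = Path("phase_maps")
out.mkdir(exist_ok=True)
for shift_um in (-10.0, 0.0, 10.0):
    phase_map = bessel_tiled_map(
        TilingShift(shift_um), annulus, grid, cal,
        wavelength=0.488, medium_index=1.33, carrier_offset_um=20.0,
    )
    path = out / f"bessel_shift_{shift_um:+.0f}um.png"
    write_phase_map(path, phase_map, shift_um=shift_um,
                    na_inner=0.14, na_outer=0.35)
    frac_pi = (phase_map.values > 0).mean()
    print(f"{path}  ({frac_pi:.1%} of pixels at phase pi)")
# Each file is a complete recipe for one tile position; cycling through them
# at the SLM frame rate tiles the sheet with no moving parts.
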