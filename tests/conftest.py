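import numpy as np
import pytest

from tilesheet import (
    AnnulusSpec,
    GridSpec,
    OpticalConfig,
    PupilCalibration,
    SlmGrid,
)


@pytest.fixture(scope="session")
def cfg_fast() -> OpticalConfig:
    """Coarse but Nyquist-valid sampling for quick propagation tests."""
    return OpticalConfig(grid=GridSpec(n_transverse=256, step_transverse=0.15,
                                       n_axial=81, step_axial=0.5))


@pytest.fixture(scope="session")
def cfg_full() -> OpticalConfig:
    """Production sampling used for the headline beam metrics."""
    return OpticalConfig(grid=GridSpec(n_transverse=512, step_transverse=0.135,
                                       n_axial=161, step_axial=0.25))


@pytest.fixture(scope="session")
def bessel_annulus() -> AnnulusSpec:
    """The high-resolution Bessel annulus (NA 0.14-0.35)."""
    return AnnulusSpec(0.14, 0.35)


@pytest.fixture
def slm_grid() -> SlmGrid:
    return SlmGrid(n_cols=256, n_rows=256, pixel_pitch=13.62)


@pytest.fixture
def pupil_cal() -> PupilCalibration:
    # 256 px grid -> na_max 0.55 on the inscribed circle
    return PupilCalibration(na_per_px=0.55 / 128)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
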