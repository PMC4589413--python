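import numpy as np
import pytest

from hemisym.synthetic import SimulationConfig, generate_homotopic_series, generate_symmetric_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_template():
    cfg = SimulationConfig(grid_shape=(16, 16, 16), n_timepoints=10, seed=7, smoothing_fwhm_mm=3.0)
    return generate_symmetric_template(cfg)


def make_series(shape=(8, 8, 8), nt=200, rho=0.0, phi=0.0, fwhm=0.0, seed=0, voxel=1.0):
    cfg = SimulationConfig(
        grid_shape=shape,
        n_timepoints=nt,
        rho_map=rho,
        ar_coefficient=phi,
        smoothing_fwhm_mm=fwhm,
        voxel_size_mm=voxel,
        seed=seed,
    )
    return generate_homotopic_series(cfg)
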