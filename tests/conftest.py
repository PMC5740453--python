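import numpy as np
import pytest

import saxstt as st
from saxstt._kernels import warmup


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    # compile the fused kernels once so individual tests time only themselves
    warmup()


@pytest.fixture(scope="session")
def detector():
    return st.DetectorGeometry()


@pytest.fixture(scope="session")
def zonal_basis():
    return st.SHBasisSpec((0, 2, 4, 6))


def random_volume(shape, basis, seed, coeff_scale=0.3, coeff_loc=0.5):
    """Random voxel fields used by gradient-certification style tests."""
    rng = np.random.default_rng(seed)
    vol = st.TensorVolume.zeros(shape, basis)
    vol.coeffs[...] = rng.normal(coeff_loc, coeff_scale, vol.coeffs.shape)
    vol.theta[...] = rng.uniform(0.3, 2.8, shape)
    vol.phi[...] = rng.uniform(-3.0, 3.0, shape)
    return vol


@pytest.fixture(scope="session")
def small_stack(detector, zonal_basis):
    """Noiseless 5-orientation stack from a random 6^3 volume."""
    truth = random_volume((6, 6, 6), zonal_basis, seed=42)
    grid = st.orientation_grid(alpha_step=36.0, beta_range=(15.0, 15.0))
    spec = st.PhantomSpec(shape=(6, 6, 6))
    data = st.simulate_stack(truth, grid, detector, spec, noise=False)
    return truth, grid, data


@pytest.fixture(scope="session")
def two_domain_16(detector):
    """The reference 16^3 two-domain phantom with its noiseless 240-proj stack."""
    spec = st.PhantomSpec(shape=(16, 16, 16), n_domains=2, seed=3)
    volume, truth = st.make_phantom(spec)
    grid = st.orientation_grid()
    data = st.simulate_stack(volume, grid, detector, spec, noise=False)
    return volume, truth, grid, data
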