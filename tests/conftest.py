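import numpy as np
import pytest

import coilpeaks as cp


@pytest.fixture(scope="session")
def library():
    return cp.DihedralLibrary.default()


@pytest.fixture(scope="session")
def surface(library):
    return cp.ShiftSurface.default(library)


@pytest.fixture(scope="session")
def windows():
    return cp.ClassWindows.default()


@pytest.fixture(scope="session")
def ala_ensemble(library):
    """10k-conformer poly-alanine host ensemble, reused across tests."""
    return cp.sample_ensemble(library, "AAAAAAAAAAA", 10_000, seed=7)


@pytest.fixture()
def single_gauss_spectrum():
    """One noiseless 2D Gaussian at (53.0, 18.5), FWHM 3.0/3.0, unit volume."""
    spec = cp.SyntheticSpec(
        components=[cp.ComponentSpec(center=(53.0, 18.5), fwhm=(3.0, 3.0), fraction=1.0)]
    )
    a1 = cp.Axis.from_range("13C-CA", 44.0, 62.0, 0.1)
    a2 = cp.Axis.from_range("13C-CB", 9.0, 28.0, 0.1)
    spectrum, truth = cp.simulate_crosspeak(spec, a1, a2)
    return spectrum, truth


def assert_spectra_close(a, b, rtol=1e-9, atol=1e-12):
    np.testing.assert_allclose(a.intensity, b.intensity, rtol=rtol, atol=atol)
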