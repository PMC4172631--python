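import numpy as np
import pytest

from lodosim.ct_forward import CalibrationModel, ElectronicNoisePool, Geometry, LineIntegralSinogram


@pytest.fixture(scope="session")
def pool20():
    """Synthetic non-Gaussian electronic pool with sigma_e exactly 20 counts."""
    return ElectronicNoisePool.synthetic(seed=3, sigma_e=20.0)


@pytest.fixture(scope="session")
def flat_field():
    """A degenerate 1-angle geometry with 10^5 bins at zero attenuation:
    every bin sees the full flux, ideal for Monte-Carlo moment checks."""
    n = 100_000
    geom = Geometry(n_angles=1, n_bins=n, bin_spacing_mm=1e9 / n)
    return LineIntegralSinogram(p=np.zeros((1, n)), geometry=geom)


def make_calib(n0_per_mas, pool):
    return CalibrationModel(n0_per_mas=n0_per_mas, electronic_pool=pool)
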