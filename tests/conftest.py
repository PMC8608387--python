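import numpy as np
import pytest

from txnoise import GeneParams, ModelSpec, NoiseSpec, simulate_population


@pytest.fixture(scope="session")
def m1_gamma_population():
    """M1 population with the Gamma(5,10) transcription-noise setting
    (theoretical extrinsic noise 0.2), dual-reporter mode, 500 cells."""
    return simulate_population(
        ModelSpec("M1"), GeneParams.of(KN=50.0, KM=10.0, deltaM=1.0),
        {"KN": NoiseSpec.gamma(5.0, 10.0), "KM": NoiseSpec.gamma(8.0, 1.25)},
        n_cells=500, dual_reporter=True, seed=20260917)


@pytest.fixture(scope="session")
def m1_fixed_population():
    """M1 population with all parameters fixed (no extrinsic noise)."""
    return simulate_population(
        ModelSpec("M1"), GeneParams.of(KN=50.0, KM=10.0, deltaM=1.0),
        None, n_cells=4000, dual_reporter=True, seed=4711)


def normalized_cov(x, y):
    return np.cov(x, y, ddof=1)[0, 1] / (x.mean() * y.mean())
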