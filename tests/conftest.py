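import numpy as np
import pytest

from hkspeckle.models import HKParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


# mean HK parameter triples per (alpha, rho) grid cell of the reference
# experiment, with the intensity SNR each one implies (2 d.p.)
REFERENCE_CELLS = [
    # (alpha, rho, epsilon, sigma, c, snr)
    (0.1, 1, 0.01, 0.17, 1.00, 0.58),
    (1, 1, 0.01, 0.26, 1.92, 0.70),
    (10, 1, 0.01, 0.29, 12.84, 0.93),
    (100, 1, 0.01, 0.30, 100.00, 0.99),
    (0.1, 5, 0.10, 0.21, 1.25, 0.65),
    (1, 5, 0.36, 0.16, 5.61, 0.97),
    (10, 5, 0.54, 0.16, 5.69, 1.09),
    (100, 5, 0.52, 0.13, 6.38, 1.15),
    (0.1, 10, 0.14, 0.20, 2.55, 0.78),
    (1, 10, 0.53, 0.14, 6.70, 1.12),
    (10, 10, 0.60, 0.11, 40.26, 1.02),
    (100, 10, 0.69, 0.11, 14.02, 1.21),
    (0.1, 50, 0.01, 0.25, 6.82, 0.88),
    (1, 50, 0.33, 0.15, 6.82, 0.96),
    (10, 50, 0.01, 0.26, 2.51, 0.75),
    (100, 50, 0.11, 0.16, 1.10, 0.67),
    (0.1, 100, 0.24, 0.26, 100.00, 0.99),
    (1, 100, 0.27, 0.23, 3.08, 0.85),
    (10, 100, 0.10, 0.24, 1.27, 0.65),
    (100, 100, 0.09, 0.20, 1.10, 0.63),
]


@pytest.fixture(scope="session")
def reference_cells():
    return REFERENCE_CELLS


@pytest.fixture(scope="session")
def reference_hk_params():
    return [HKParams(e, s, c) for (_, _, e, s, c, _) in REFERENCE_CELLS]
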