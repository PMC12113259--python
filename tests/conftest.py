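import numpy as np
import pytest

from optorho import KineticParams, PulseProtocol, build_phenotype_map, calibrate_weight


@pytest.fixture(scope="session")
def kin():
    """Published point estimates: k2 = 0.014/s, koff = 0.08/s."""
    return KineticParams(k2=0.014, rho=0.0, koff_sensor=0.08)


@pytest.fixture(scope="session")
def weight(kin):
    """RhoA-vs-Cdc42 weight calibrated on the sustained-step reference."""
    return calibrate_weight(kin)


@pytest.fixture(scope="session")
def train30():
    """Standard 30 s-period fold-1.5 train over 10 minutes."""
    return PulseProtocol.regular(30.0, 1.5, 600.0)


@pytest.fixture(scope="session")
def phenotype_map(kin, weight):
    """Full-resolution phenotype map shared by the phenotype and acceptance tests."""
    return build_phenotype_map(
        np.arange(0.0, 1.5001, 0.05), np.arange(10.0, 120.001, 5.0), kin, weight
    )
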