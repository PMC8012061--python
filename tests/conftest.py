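import numpy as np
import pytest

from poolkin import (
    DelayedSRPKinetics,
    FlashKinetics,
    Model1Params,
    NoiseSpec,
    TimeGrid,
)

# WT-like flash kinetics: fast RRP burst, slow SRP burst, sustained rate
WT_KIN = FlashKinetics(A1=50.0, tau1=0.015, A2=30.0, tau2=0.3, A3=20.0)

# delayed-SRP kinetics typical of ubMunc13-2 overexpression without Syt-7
DELAYED_KIN = DelayedSRPKinetics(A1=40.0, tau1=0.02, SRP=300.0,
                                 tau_slow_delay=0.5, A3=0.0)

# 60-ms-readout priming parameters for the two genotypes: the wild type has
# a slow depriming rate and slight post-stimulation overfilling, the
# knock-out deprimes twice as fast and underfills after stimulation
WT_MODEL1 = Model1Params(k1dp=3.21, k_minus1=0.043)
WT_K1DP_AFTER = 3.78
KO_MODEL1 = Model1Params(k1dp=3.07, k_minus1=0.091)
KO_K1DP_AFTER = 1.90

RECOVERY_INTERVALS = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 120.0])


@pytest.fixture
def grid():
    return TimeGrid(t_start=-0.5, t_end=5.0, dt=1e-3)


@pytest.fixture
def noiseless():
    return NoiseSpec(sigma_cm=0.0, sigma_amp=0.0, seed=0)


@pytest.fixture
def wt_kinetics():
    return WT_KIN


@pytest.fixture
def delayed_kinetics():
    return DELAYED_KIN
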