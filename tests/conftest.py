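"""Shared fixtures: the study conditions used across the suite.

Values are the measured/fitted quantities of the reference 15-bp DNA
system: free and bound Na+ diffusion coefficients, ion count per duplex,
buffer composition, and the BPP-LED acquisition timing.
"""

import numpy as np
import pytest

from iondiff import (CompetitionSystem, ExchangeParameters, NoiseModel,
                     PulseParams, R2ExchangeParameters)

# reference-system quantities (SI units)
D_F = 1.251e-9            # free Na+ diffusion, m^2/s
D_B = 0.71e-9             # ion-atmosphere Na+ diffusion, m^2/s
A_IONS = 25.5             # Na+ ions per DNA duplex
NA_BUFFER = 0.020         # mol/L
Q_TRUE = 0.58             # Na+/K+ preference quotient
R_F = 17.3                # free-state R2, s^-1
R_B = 73.0                # ion-atmosphere R2, s^-1
C_DNA_MAX = 1.74e-3       # mol/L, highest DNA concentration of the titration
NA_TOTAL = NA_BUFFER + A_IONS * C_DNA_MAX     # 64.37 mM
T_CAPACITY = A_IONS * C_DNA_MAX               # 44.37 mM


@pytest.fixture
def pulse_params():
    """1 ms bipolar lobes (delta = 2 ms), Delta = 20 ms, tau = 0.2 ms."""
    return PulseParams(delta=2e-3, Delta=20e-3, tau=0.2e-3, nucleus="23Na")


@pytest.fixture
def exchange_params():
    return ExchangeParameters(D_f=D_F, D_b=D_B, a=A_IONS, Na_buffer=NA_BUFFER)


@pytest.fixture
def r2_params():
    return R2ExchangeParameters(R_f=R_F, R_b=R_B, a=A_IONS, Na_buffer=NA_BUFFER)


@pytest.fixture
def competition_template():
    return CompetitionSystem(Na_total=NA_TOTAL, K_total=0.0,
                             T_capacity=T_CAPACITY, Q=Q_TRUE,
                             D_f=D_F, D_b=D_B)


@pytest.fixture
def noiseless():
    return NoiseModel(sigma=0.0, seed=0, n_replicates=1)
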