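"""Shared fixtures: canonical synthetic study conditions."""
import numpy as np
import pytest

from gp32filament.polymer import PolymerParams
from gp32filament.synthetic import GeneratorSpec

# canonical constant-force binding trace (15 pN / 100 nM-like):
# fast compaction then two elongations, rates separated ~10x
TRI_AMPS = (-250.0, 120.0, 150.0)
TRI_RATES = (0.5, 0.05, 0.005)
TRI_X0 = 2800.0
TRI_DURATION = 1200.0

FJC_PARAMS = PolymerParams(0.510, 8100, 1.9)     # noncooperative truncate
WLC_PARAMS = PolymerParams(0.41, 8100, 20.0)     # saturated WT filament


@pytest.fixture
def noiseless_spec():
    return GeneratorSpec(seed=11, noise_sd=0.0, dt=0.25)


@pytest.fixture
def noisy_spec():
    """5-nm extension noise: 2% of the largest canonical amplitude."""
    return GeneratorSpec(seed=23, noise_sd=5.0, dt=0.25)


@pytest.fixture
def fec_force_grid():
    return np.linspace(0.5, 10.0, 50)
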