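import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from potsense import (
    DilutionProtocol,
    ElectrolyteComposition,
    IonSpecies,
    NoiseModel,
    SensorParams,
)

TMA = IonSpecies("TMA", +1, 60.12)
K = IonSpecies("K", +1, 39.10)
NA = IonSpecies("Na", +1, 22.99)
CA = IonSpecies("Ca", +2, 40.08)
CL = IonSpecies("Cl", -1, 35.45)


@pytest.fixture
def tma():
    return TMA


@pytest.fixture
def potassium():
    return K


@pytest.fixture
def ideal_sensor():
    """Theoretical-Nernstian TMA electrode with Table-style K selectivity."""
    return SensorParams(TMA, E0_mV=400.0, selectivities={K: 10.0**-1.12})


@pytest.fixture
def kcl_background():
    """0.1 mM KCl fixed-interference background."""
    return ElectrolyteComposition({K: 1e-4, CL: 1e-4})


@pytest.fixture
def fim_protocol(kcl_background):
    """Stepwise dilution 0.1 M down to 10 nM in the KCl background."""
    levels = tuple(10.0 ** -np.arange(1.0, 9.0))
    return DilutionProtocol(levels, dwell_s=30.0, background=kcl_background)


@pytest.fixture
def quiet():
    return NoiseModel()  # all-zero noise, seed 0
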