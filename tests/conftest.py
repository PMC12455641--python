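import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from carokin.dataprep import reference_condition_fluxes
from carokin.kinetics import compile_model, sample_particle
from carokin.network import load_network, propagate_fluxes
from carokin.thermo import ThermoSampler, load_thermo_table


@pytest.fixture(scope="session")
def model():
    return load_network()


@pytest.fixture(scope="session")
def thermo():
    return load_thermo_table()


@pytest.fixture(scope="session")
def v_ref(model):
    ff = reference_condition_fluxes()
    return propagate_fluxes(model, {k: v[0] for k, v in ff.items()})


@pytest.fixture(scope="session")
def sampler(model, thermo):
    return ThermoSampler(model, thermo)


@pytest.fixture(scope="session")
def compiled_levels(model):
    return {lvl: compile_model(model, lvl) for lvl in ("simple", "regulated", "detailed")}


@pytest.fixture(scope="session")
def particle_factory(sampler, v_ref, compiled_levels):
    """Deterministic particle supply shared across tests."""

    def make(level="simple", seed=0, tilt=None):
        cm = compiled_levels[level]
        refstate = sampler.sample(10_000 + seed)
        return cm, sample_particle(cm, refstate, v_ref, 20_000 + seed, tilt=tilt)

    return make
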