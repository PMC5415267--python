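import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from mesopop.model import (
    AdaptationKernel,
    NetworkSpec,
    PopulationParams,
    StimulusStep,
)

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


def single_population_spec(pop: PopulationParams, mu: float,
                           J_w: float = 0.0, delay: float = 0.001,
                           tau_s: float = 0.003) -> NetworkSpec:
    """One population with optional full self-coupling and constant drive."""
    return NetworkSpec(
        populations=[pop],
        p=[[1.0 if J_w else 0.0]],
        w=[[J_w]],
        delay=[[delay]],
        tau_s=[tau_s],
        stimulus=[[StimulusStep(0.0, float("inf"), mu)]],
    )


@pytest.fixture
def lif_pop():
    """Table-default LIF population (no adaptation)."""
    return PopulationParams(N=500)


@pytest.fixture
def deadtime_poisson_pop():
    """Absolute-refractory Poisson neuron: GLM variant, no kernels."""
    return PopulationParams(N=200, model_variant="GLM")


@pytest.fixture
def adapting_kernel():
    return AdaptationKernel(((1.5, 0.01), (1.5, 1.0)), t_ref=0.004)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
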