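import numpy as np
import pytest

from clonehap import (
    LibrarySpec,
    PipelineParams,
    SimConfig,
    run_simulated,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_single_clone_run():
    """Noise-free single-clone sample, phased end to end."""
    cfg = SimConfig(
        reference_length=30_000,
        germline_rate=0.001,
        somatic_rate=0.01,
        n_subclones=1,
        proportions=(1.0,),
        libraries=(LibrarySpec(1000.0, 100, 60.0),),
        epsilon=0.0,
        seed=7,
    )
    return run_simulated(cfg, PipelineParams(seed=7))


@pytest.fixture(scope="session")
def mixture_run():
    """Default three-clone mixture at reduced scale, phased end to end."""
    cfg = SimConfig(
        reference_length=60_000,
        n_subclones=3,
        proportions=(0.3, 0.5, 0.2),
        libraries=(
            LibrarySpec(1000.0, 250, 100.0),
            LibrarySpec(1500.0, 250, 50.0),
            LibrarySpec(2000.0, 250, 50.0),
        ),
        epsilon=0.01,
        seed=11,
    )
    return run_simulated(cfg, PipelineParams(seed=11))
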