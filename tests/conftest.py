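import numpy as np
import pytest

from glossjoint import (
    ModelSpec,
    PerceptualScales,
    build_lattice,
    build_schedule,
    enumerate_pairs,
)
from glossjoint.studies import simulate_observer_trials


@pytest.fixture(scope="session")
def lattice5():
    return build_lattice(5, 5, 3)


@pytest.fixture(scope="session")
def pairs5(lattice5):
    return enumerate_pairs(lattice5)


@pytest.fixture(scope="session")
def schedule900(pairs5):
    return build_schedule(pairs5, repetitions=3, seed=11, task="gloss")


@pytest.fixture(scope="session")
def additive_scales():
    return PerceptualScales(
        psi_gloss=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        psi_lightness=np.array([0.0, -0.3, -0.6, -0.9, -1.28]),
        sigma=1.0,
    )


@pytest.fixture(scope="session")
def additive_spec():
    return ModelSpec("additive", "gloss")


@pytest.fixture(scope="session")
def contaminated_trials():
    """One simulated experiment from an additive observer with w = -0.32."""
    trials, observer = simulate_observer_trials("additive_contaminated", -0.32, seed=42)
    return trials, observer
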