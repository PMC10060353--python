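import numpy as np
import pytest

from crowddiff import (
    ExperimentConfig,
    InteractionParams,
    ObservationSet,
    experiment_preset,
    simulate,
)

MORSE = InteractionParams(D_e=0.00021, a=3.5, r0=1.0, phi="exp")
NO_INTERACTION = InteractionParams(D_e=0.0, a=1.0)


@pytest.fixture(scope="session")
def morse_params() -> InteractionParams:
    return MORSE


def random_positions(
    rng: np.random.Generator, n: int, spread: float = 4.0, min_dist: float = 0.05
) -> np.ndarray:
    """Random configuration with all pair distances kept away from zero."""
    while True:
        pos = spread * rng.random((n, 2))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            return pos


@pytest.fixture(scope="session")
def brownian_obs() -> ObservationSet:
    """Interaction-free trajectories: 40 particles, 50 intervals of 300 s."""
    config = ExperimentConfig(
        N=40,
        duration=15_000.0,
        obs_interval=300.0,
        interaction=NO_INTERACTION,
        sigma=0.01,
        h=300.0,
        seed=11,
        confined=False,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def crowded_obs():
    """A small crowded Morse system observed every 5 minutes for 2 h."""
    config = experiment_preset(
        "exp2", N=64, duration=7200.0, obs_interval=300.0, seed=5
    )
    return simulate(config), config
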