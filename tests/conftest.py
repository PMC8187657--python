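"""Shared fixtures: small deterministic ensembles and datasets.

Everything is generated at test time; the polymer configurations here are
scaled down (fewer chains, shorter relaxation) from the package defaults to
keep the suite fast while preserving the statistical character the tests
rely on.
"""

import numpy as np
import pytest

from tracenet.labeling import ContactRule, NoiseSpec, label_binary_contact
from tracenet.polymer_sim import SimulationConfig, simulate_ensemble
from tracenet.trace_data import build_dataset


def small_sim_config(n_examples: int = 1000, seed: int = 0, **overrides):
    frames = min(50, n_examples)
    base = dict(
        n_chains=max(1, n_examples // frames),
        frames_per_chain=frames,
        steps_per_frame=25,
        burn_in_steps=1000,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_ensemble():
    """1,500 conformations from a scaled-down simulation."""
    return simulate_ensemble(small_sim_config(n_examples=1500, seed=11))


@pytest.fixture(scope="session")
def ensemble_coords(small_ensemble):
    return small_ensemble.coords()


@pytest.fixture(scope="session")
def ensemble_distances(ensemble_coords):
    c = ensemble_coords
    return np.linalg.norm(c[:, :, None, :] - c[:, None, :, :], axis=-1)


@pytest.fixture(scope="session")
def contact_dataset(small_ensemble, ensemble_distances):
    """Binary-contact labels at 50% noise on the small ensemble."""
    labels = label_binary_contact(
        small_ensemble, ContactRule(), NoiseSpec(0.5), seed=12
    )
    return build_dataset(ensemble_distances, labels, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
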