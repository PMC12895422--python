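"""Shared fixtures: small molecules, orbital sets, datasets, one trained model.

Everything is generated programmatically at session scope; the expensive
artifacts (SCF runs, the 16-image dataset, one full training run) are
computed once and reused across test modules.
"""

import numpy as np
import pytest

from molorbimage import (ExcitationImageModel, FixtureSpec, TrainingConfig,
                         generate_fixtures, run_scf, sad_guess)
from molorbimage.fixtures import DEFAULT_TRAIN_POOL, pool_molecule


@pytest.fixture(scope="session")
def h2_scf():
    return run_scf(pool_molecule("H2"))


@pytest.fixture(scope="session")
def h2o_scf():
    return run_scf(pool_molecule("H2O"))


@pytest.fixture(scope="session")
def lih_scf():
    return run_scf(pool_molecule("LiH"))


@pytest.fixture(scope="session")
def pool_scf_orbitals():
    """Converged orbitals for the default training pool species."""
    return {name: run_scf(pool_molecule(name)) for name in DEFAULT_TRAIN_POOL}


@pytest.fixture(scope="session")
def pool_sad_orbitals():
    return {name: sad_guess(pool_molecule(name)) for name in DEFAULT_TRAIN_POOL}


@pytest.fixture(scope="session")
def fixture_dataset():
    """16 jittered molecules, SAD orbitals, beta=10, N_MO=8, noisy targets."""
    spec = FixtureSpec(n_molecules=16, seed=3)
    molecules, dataset = generate_fixtures(spec)
    return molecules, dataset


@pytest.fixture(scope="session")
def trained_results(fixture_dataset):
    """One full training run on the 16-image fixture (memorization regime).

    All images in the training split; the plateau schedule is driven by the
    training loss. Reused by the protocol, history and memorization tests.
    """
    _, dataset = fixture_dataset
    config = TrainingConfig(batch_size=16, max_epochs=800, seed=0,
                            split=(1.0, 0.0, 0.0))
    model = ExcitationImageModel(dataset, config=config)
    return model.fit()
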