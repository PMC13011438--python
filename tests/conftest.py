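import logging

import numpy as np
import pytest

import somkit
from somkit import fixtures as fx

logging.getLogger("somkit").setLevel(logging.ERROR)


def perceive(smiles: str, mol_id: str = "m") -> somkit.MoleculeRecord:
    return somkit.perceive_molecule(smiles, mol_id)


@pytest.fixture(scope="session")
def benzene():
    return perceive("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def ethanol():
    return perceive("CCO", "ethanol")


@pytest.fixture(scope="session")
def methane():
    return perceive("C", "methane")


@pytest.fixture(scope="session")
def neopentane():
    return perceive("CC(C)(C)C", "neopentane")


@pytest.fixture(scope="session")
def butane():
    return perceive("CCCC", "butane")


@pytest.fixture(scope="session")
def small_fixture_set():
    """60 labeled synthetic molecules, deterministic."""
    return fx.generate(fx.FixtureSpec(n_molecules=60, seed=11))


@pytest.fixture(scope="session")
def tiny_model(small_fixture_set):
    """A small but real trained model shared across tests."""
    cfg = somkit.TrainingConfig(n_trees=40, seed=5)
    return somkit.train(small_fixture_set, cfg)


@pytest.fixture(scope="session")
def random_bit_vectors():
    rng = np.random.default_rng(42)
    return (rng.random((500, 160)) < 0.12).astype(np.uint8)
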