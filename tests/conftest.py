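import numpy as np
import pytest

from qtaimnet import Molecule, RepresentationConfig, ReadoutConfig, build_model
from qtaimnet.surrogate_data import chon_params, generate_dataset, generate_geometry


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rigid_transform(mol: Molecule, rng: np.random.Generator) -> Molecule:
    Q = random_rotation(rng)
    t = rng.uniform(-5, 5, size=3)
    return Molecule(mol.Z, mol.R @ Q.T + t, id=mol.id)


def permute(mol: Molecule, perm: np.ndarray) -> Molecule:
    Z = tuple(mol.Z[i] for i in perm)
    return Molecule(Z, mol.R[perm], id=mol.id)


@pytest.fixture
def water() -> Molecule:
    return Molecule(
        (8, 1, 1),
        np.array([[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399, 0.9266, 0.0]]),
        id="water",
    )


@pytest.fixture(scope="session")
def chon():
    return chon_params(seed=0)


@pytest.fixture(scope="session")
def small_dataset(chon):
    """120 labeled surrogate records, reused across tests."""
    records, _ = generate_dataset(120, chon, seed=11)
    return records


@pytest.fixture(scope="session")
def random_molecules(chon):
    return [generate_geometry(chon, seed=1000 + k) for k in range(30)]


@pytest.fixture(scope="session")
def tiny_rep_config():
    return RepresentationConfig(n=16, n_interactions=2, n_rbf=8, seed=7)


@pytest.fixture(scope="session")
def tiny_1p_model(tiny_rep_config):
    rc = ReadoutConfig(mode="ElementalAIMwise", elements=(1, 6, 7, 8), hidden_sizes=(8, 8))
    return build_model(tiny_rep_config, rc, "q", "e")


@pytest.fixture(scope="session")
def tiny_2p_model(tiny_rep_config):
    rc = ReadoutConfig(mode="ElementalPairAIMwise", elements=(1, 6, 7, 8), hidden_sizes=(8, 8))
    return build_model(tiny_rep_config, rc, "delta", "e")
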