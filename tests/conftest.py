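"""Shared fixtures: synthetic structures with known ground truth."""

import numpy as np
import pytest

from claudinkit import (
    HelixSpec,
    KinkSpec,
    make_domain_pair,
    make_helix_bundle,
    make_ideal_helix,
    make_kinked_helix,
)

# 37 residues with vertex 19 gives two 18-residue arms, each spanning an
# exact number of helical turns (18 × 100° = 5 turns)
N_RES = 37
VERTEX = 19
PROXIMAL = (1, VERTEX - 1)
DISTAL = (VERTEX + 1, N_RES)


@pytest.fixture(scope="session")
def helix30():
    return make_ideal_helix(HelixSpec(n_residues=30), chain="A")


@pytest.fixture(scope="session")
def kinked_factory():
    def build(theta, chain="A", azimuth=0.0, n=N_RES, vertex=VERTEX):
        spec = KinkSpec(
            helix=HelixSpec(n_residues=n),
            vertex_index=vertex,
            kink_angle=theta,
            kink_plane_azimuth=azimuth,
        )
        return make_kinked_helix(spec, chain=chain)

    return build


@pytest.fixture(scope="session")
def domain_pair_5A():
    """Core helix + mobile helix translated by exactly 5 Å, no noise."""
    core = make_ideal_helix(HelixSpec(n_residues=30), chain="A")
    mobile = make_ideal_helix(
        HelixSpec(n_residues=20, origin=(12.0, 0.0, 0.0)), chain="A", start_residue=41
    )
    return make_domain_pair(core, mobile, translation=(5.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def bundle4():
    return make_helix_bundle(4, [0.0, 0.0, 0.0, 0.0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform-ish random proper rotation via QR with sign fix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
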