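"""Shared fixtures: small hand-built molecules and query fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from dualphore.chem import Atom, Bond, Molecule3D
from dualphore.pharmacophore import carm1_like_query


def _hexagon(radius: float = 1.39, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    angles = np.deg2rad(np.arange(6) * 60.0)
    pts = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(6)], axis=1
    )
    return pts + np.asarray(center)


def make_benzene(center=(0.0, 0.0, 0.0), aromatic_flags: bool = True) -> Molecule3D:
    coords = _hexagon(center=center)
    atoms = [Atom("C", 0, tuple(p)) for p in coords]
    bonds = [Bond(i, (i + 1) % 6, 1, aromatic_flags) for i in range(6)]
    return Molecule3D("benzene", atoms, bonds)


@pytest.fixture
def benzene() -> Molecule3D:
    return make_benzene()


@pytest.fixture
def methanol() -> Molecule3D:
    # C-O-H with explicit hydroxyl hydrogen; methyl hydrogens omitted
    atoms = [
        Atom("C", 0, (0.0, 0.0, 0.0)),
        Atom("O", 0, (1.43, 0.0, 0.0)),
        Atom("H", 0, (1.75, 0.89, 0.0)),
    ]
    bonds = [Bond(0, 1), Bond(1, 2)]
    return Molecule3D("methanol", atoms, bonds)


@pytest.fixture
def hexane() -> Molecule3D:
    # extended all-carbon chain, 1.54 A spacing along x
    atoms = [Atom("C", 0, (1.54 * i, 0.0, 0.0)) for i in range(6)]
    bonds = [Bond(i, i + 1) for i in range(5)]
    return Molecule3D("n-hexane", atoms, bonds)


@pytest.fixture
def naphthalene() -> Molecule3D:
    """Two fused six-rings sharing the (4,5) bond; geometry is schematic."""
    coords = np.zeros((10, 3))
    coords[:6] = _hexagon()
    shifted = _hexagon(center=(2.41, 0.0, 0.0))
    coords[6:] = shifted[[1, 2, 3, 4]]
    atoms = [Atom("C", 0, tuple(p)) for p in coords]
    ring_a = [(i, (i + 1) % 6) for i in range(6)]
    ring_b = [(5, 6), (6, 7), (7, 8), (8, 9), (9, 4)]
    bonds = [Bond(i, j, 1, True) for i, j in ring_a + ring_b]
    return Molecule3D("naphthalene", atoms, bonds)


@pytest.fixture
def four_feature_query():
    return carm1_like_query()
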