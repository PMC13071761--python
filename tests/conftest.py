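"""Shared fixtures: toy systems and coupled gate/H-bond ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from ptmgate.model_io import Atom, MolecularSystem, Trajectory
from ptmgate.synthetic import make_synthetic_system


@pytest.fixture
def toy_system() -> MolecularSystem:
    """4 atoms over 2 residues, with charges for energy tests."""
    atoms = [
        Atom(1, "N", "N", 1, "ALA", "A", charge=-0.3, lj_sigma=0.32, lj_epsilon=0.17, mass=14.007),
        Atom(2, "CA", "C", 1, "ALA", "A", charge=0.1, lj_sigma=0.34, lj_epsilon=0.1, mass=12.011),
        Atom(3, "CA", "C", 2, "GLY", "A", charge=0.1, lj_sigma=0.34, lj_epsilon=0.1, mass=12.011),
        Atom(4, "O", "O", 2, "GLY", "A", charge=-0.5, lj_sigma=0.30, lj_epsilon=0.21, mass=15.999),
    ]
    return MolecularSystem(atoms, {"all": [1, 2]})


@pytest.fixture
def cysteine_system() -> MolecularSystem:
    """11 cysteines plus padding residues, matching the OpcA site count."""
    resnames = {i: "CYS" for i in range(1, 12)}
    return make_synthetic_system(15, resnames=resnames)


def make_hbond_gate_fixture(
    series: np.ndarray,
    closed_cut: float = 0.4,
) -> tuple[Trajectory, np.ndarray]:
    """A trajectory whose ASP33–ARG243 bond geometry exists exactly in closed frames.

    Gate residues carry CB side-chain atoms whose pair distance equals the
    series; in frames with series < closed_cut the ASP33 acceptor (OD1) sits
    in perfect bond geometry (0.30 nm, 0°) from the ARG243 donor (NH1), in
    other frames 1.0 nm away.  Returns the trajectory and a boolean
    closed-frame mask.
    """
    n_res = 243
    extra = {
        33: [("CB", "C"), ("OD1", "O")],
        37: [("CB", "C")],
        241: [("CB", "C")],
        243: [("CB", "C"), ("NH1", "N"), ("HH11", "H")],
    }
    resnames = {33: "ASP", 37: "ARG", 241: "GLU", 243: "ARG"}
    system = make_synthetic_system(n_res, resnames=resnames, extra_atoms=extra)
    rng = np.random.default_rng(99)
    base = rng.uniform(0.0, 8.0, size=(system.n_atoms, 3))

    # park the 33/37 and 241/243 CB atoms so only the embedded pair is closest
    cb33 = system.atom_index("A", 33, "CB")
    cb37 = system.atom_index("A", 37, "CB")
    cb241 = system.atom_index("A", 241, "CB")
    cb243 = system.atom_index("A", 243, "CB")
    base[cb33] = [0.0, 0.0, 0.0]
    base[cb37] = [0.0, 5.0, 0.0]
    base[cb241] = [0.0, 5.0, 5.0]

    od1 = system.atom_index("A", 33, "OD1")
    nh1 = system.atom_index("A", 243, "NH1")
    hh11 = system.atom_index("A", 243, "HH11")

    n_frames = len(series)
    coords = np.repeat(base[None], n_frames, axis=0)
    u = np.array([1.0, 0.0, 0.0])
    coords[:, cb243] = np.array([0.0, 0.0, 0.0]) + np.outer(series, [0.0, 0.0, 1.0])
    closed = series < closed_cut
    for f in range(n_frames):
        origin = np.array([3.0, 3.0, 3.0])
        coords[f, nh1] = origin
        coords[f, hh11] = origin + 0.10 * u
        coords[f, od1] = origin + (0.30 if closed[f] else 1.00) * u
    return Trajectory(system=system, coordinates=coords), closed
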