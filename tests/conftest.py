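"""Shared fixtures: small synthetic structures and cached pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from spaceball.cavity import run_spaceball
from spaceball.descriptors import compute_descriptors
from spaceball.fixtures import make_hollow_sphere
from spaceball.lattice import ProbeParams
from spaceball.structure import Atom, Residue, Structure
from spaceball.surface import compute_surface_metrics
from spaceball.tables import element_mass

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def single_atom_structure(coords=(0.0, 0.0, 0.0), radius=1.7, name="GLY"):
    atom = Atom(
        serial=1, name="C", element="C", coords=np.asarray(coords, dtype=float),
        vdw_radius=radius, mass=element_mass("C"), residue_name=name,
        residue_seq=1, icode="", chain_id="A",
    )
    res = Residue(name=name, seq=1, icode="", chain_id="A", atoms=[atom])
    return Structure(id="single", residues=[res])


def point_cloud_structure(points, residue_names=None, radius=1.7, chain_id="A"):
    """One single-atom pseudo-residue per point (test helper)."""
    points = np.asarray(points, dtype=float)
    names = residue_names or ["GLY"] * len(points)
    residues = []
    for i, (p, nm) in enumerate(zip(points, names), start=1):
        atom = Atom(
            serial=i, name="C", element="C", coords=p, vdw_radius=radius,
            mass=element_mass("C"), residue_name=nm, residue_seq=i, icode="",
            chain_id=chain_id,
        )
        residues.append(Residue(name=nm, seq=i, icode="", chain_id=chain_id, atoms=[atom]))
    return Structure(id="cloud", residues=residues)


@pytest.fixture(scope="session")
def default_params():
    return ProbeParams(a=0.6, r_w=1.42, n_rotations=1, seed=0)


@pytest.fixture(scope="session")
def small_sphere():
    """Sealed 10 Å shell: cheap, sealed, analytic volume."""
    structure, expected = make_hollow_sphere(radius=10.0)
    return structure, expected


@pytest.fixture(scope="session")
def sphere_run(small_sphere, default_params):
    structure, expected = small_sphere
    result = run_spaceball(structure, default_params)
    return structure, expected, result


@pytest.fixture(scope="session")
def sphere_surface(sphere_run):
    structure, expected, result = sphere_run
    metrics = compute_surface_metrics(result)
    return structure, expected, result, metrics


@pytest.fixture(scope="session")
def sphere_descriptors(sphere_surface):
    structure, expected, result, metrics = sphere_surface
    desc = compute_descriptors(metrics, result.rotated_structure)
    return structure, expected, result, metrics, desc
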