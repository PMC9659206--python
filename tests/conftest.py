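"""Shared fixtures: ideal peptide builders and small structures.

All fixtures are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from ltqkit.geomcore import place_atom
from ltqkit.structio import Atom, Structure


def build_peptide(
    n_residues: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
    res_name: str = "ALA",
    chain: str = "A",
    first_res_id: int = 1,
) -> Structure:
    """An ideal N/CA/C backbone built by internal-coordinate extension.

    Every non-terminal residue gets the requested phi/psi and the peptide
    omega; bond lengths/angles are ideal (N-CA 1.46, CA-C 1.52, C-N 1.33 A;
    111/116/121 deg).
    """
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.46, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.52, 111.0, 50.0)
    pos = [("N", first_res_id, n), ("CA", first_res_id, ca), ("C", first_res_id, c)]
    prev = {"N": n, "CA": ca, "C": c}
    for i in range(first_res_id + 1, first_res_id + n_residues):
        nn = place_atom(prev["N"], prev["CA"], prev["C"], 1.33, 116.0, psi)
        ca2 = place_atom(prev["CA"], prev["C"], nn, 1.46, 121.0, omega)
        c2 = place_atom(prev["C"], nn, ca2, 1.52, 111.0, phi)
        pos += [("N", i, nn), ("CA", i, ca2), ("C", i, c2)]
        prev = {"N": nn, "CA": ca2, "C": c2}
    atoms = [
        Atom(
            serial=k + 1,
            name=nm,
            element=nm[0],
            res_name=res_name,
            res_id=rid,
            chain=chain,
            coord=p,
        )
        for k, (nm, rid, p) in enumerate(pos)
    ]
    s = Structure(atoms=atoms, title=f"ideal peptide phi={phi} psi={psi}")
    for k in range(len(atoms) - 1):
        s.add_bond(k, k + 1)
    return s


def build_random_torsion_peptide(n_residues: int, seed: int) -> Structure:
    """Backbone with random (but chain-extension-safe) phi/psi torsions."""
    rng = np.random.default_rng(seed)
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.46, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.52, 111.0, 50.0)
    pos = [("N", 1, n), ("CA", 1, ca), ("C", 1, c)]
    prev = {"N": n, "CA": ca, "C": c}
    for i in range(2, n_residues + 1):
        psi = rng.uniform(-175, 175)
        phi = rng.uniform(-175, 175)
        nn = place_atom(prev["N"], prev["CA"], prev["C"], 1.33, 116.0, psi)
        ca2 = place_atom(prev["CA"], prev["C"], nn, 1.46, 121.0, 180.0)
        c2 = place_atom(prev["C"], nn, ca2, 1.52, 111.0, phi)
        pos += [("N", i, nn), ("CA", i, ca2), ("C", i, c2)]
        prev = {"N": nn, "CA": ca2, "C": c2}
    atoms = [
        Atom(serial=k + 1, name=nm, element=nm[0], res_name="ALA", res_id=rid,
             chain="A", coord=p)
        for k, (nm, rid, p) in enumerate(pos)
    ]
    s = Structure(atoms=atoms)
    for k in range(len(atoms) - 1):
        s.add_bond(k, k + 1)
    return s


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20, 20, 3)
    return R, t


@pytest.fixture
def helix_hexapeptide() -> Structure:
    return build_peptide(6, -57.0, -47.0)


@pytest.fixture
def strand_hexapeptide() -> Structure:
    return build_peptide(6, -120.0, 120.0)


@pytest.fixture
def toy_site():
    from ltqkit.synthgen import make_toy_active_site

    return make_toy_active_site()
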