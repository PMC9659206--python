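"""Static-structure analyses of a quinone-cofactor metal site.

Covers first-shell coordination-sphere detection, the Addison geometry
index tau for 5-coordinate complexes, Jahn-Teller axis detection, lysine
chi-angle extraction and rotamer-code classification (p/t/m letters of the
penultimate rotamer library convention), aromatic pi-stacking geometry and
van-der-Waals contact listing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geomcore import angle, dihedral, distance
from .structio import Atom, Structure, select

#: Default first-shell donor cutoff (Angstrom).  Chosen to include the long
#: axial Cu-O bond of an elongated (Jahn-Teller) site (~2.5 A) and typical
#: 2.0-2.2 A M-N bonds while excluding second-shell imidazoles at >= 3 A.
DEFAULT_COORDINATION_CUTOFF = 2.6

#: Donor elements counted as first-shell ligands.
DEFAULT_DONOR_ELEMENTS = ("N", "O", "S")

#: Canonical chi rotamer letters: p(lus) = +65, t(rans) = 180, m(inus) = -65.
CANONICAL_ROTAMERS = {"p": 65.0, "t": 180.0, "m": -65.0}

#: A chi further than this from its canonical value flags the rotamer as
#: distorted (the code letter is still assigned by nearest canonical value).
DISTORTION_FLAG_DEG = 40.0

#: Bondi-type van der Waals radii (Angstrom) used by vdw_contacts.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "CU": 1.40, "ZN": 1.39,
}

#: chi atom quadruples for a lysine-like side chain; the NZ-terminated chain
#: is shared by native Lys and the LTQ-crosslinked arm.
LYS_CHI_ATOMS = [
    ("N", "CA", "CB", "CG"),
    ("CA", "CB", "CG", "CD"),
    ("CB", "CG", "CD", "CE"),
    ("CG", "CD", "CE", "NZ"),
]

_AROMATIC_RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


@dataclass
class CoordinationSphere:
    """A metal atom with its first-shell donor atoms.

    ``distances`` are metal-ligand separations (Angstrom) sorted ascending
    with ``ligands``; ``lml_angles`` holds all n(n-1)/2 ligand-metal-ligand
    angles as ``(i, j, degrees)`` with i, j indexing ``ligands``.
    """

    metal: Atom
    ligands: list[Atom] = field(default_factory=list)
    distances: list[float] = field(default_factory=list)
    lml_angles: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    def angle_between(self, i: int, j: int) -> float:
        for a, b, ang in self.lml_angles:
            if {a, b} == {i, j}:
                return ang
        raise KeyError((i, j))


@dataclass(frozen=True)
class AddisonResult:
    """Addison geometry index of a 5-coordinate metal site.

    tau = (beta - alpha) / 60 with beta >= alpha the two largest
    ligand-metal-ligand angles: 0 for an ideal square pyramid (two trans
    basal angles of 180 deg), 1 for an ideal trigonal bipyramid (axial 180,
    equatorial 120).  ``apical_ligand`` is the donor involved in neither
    beta nor alpha.  The label thresholds (<= 0.3 square-pyramidal-like,
    >= 0.7 trigonal-bipyramidal-like) are reporting conventions of this
    package; the numeric tau is authoritative.
    """

    tau: float
    beta: float
    alpha: float
    apical_ligand: Atom | None
    label: str


@dataclass(frozen=True)
class RotamerState:
    """chi angles plus their penultimate-library-style letter code."""

    chi: tuple[float, ...]
    code: str
    max_deviation: float

    @property
    def distorted(self) -> bool:
        return self.max_deviation > DISTORTION_FLAG_DEG


@dataclass(frozen=True)
class StackingContact:
    """Ring-ring geometry: centroid distance, interplanar angle, in-plane
    centroid offset, and the boolean stacking call under the thresholds
    used."""

    centroid_distance: float
    interplanar_angle: float
    offset: float
    is_stacked: bool


def find_coordination_sphere(
    s: Structure,
    metal: Atom | int,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    donor_elements: tuple[str, ...] = DEFAULT_DONOR_ELEMENTS,
) -> CoordinationSphere:
    """Detect the first coordination shell of a metal atom.

    Ligands are N/O/S (configurable) atoms within ``cutoff`` Angstrom of
    the metal, sorted by distance.  For a histidine imidazole both ring
    nitrogens may fall inside generous cutoffs; only the nearer one is a
    donor, so per residue only the closest candidate atom of each aromatic
    N pair is kept.  An empty shell warns rather than raising.
    """
    m = s.atoms[metal] if isinstance(metal, int) else metal
    donors_up = tuple(e.upper() for e in donor_elements)
    candidates: list[tuple[float, Atom]] = []
    for a in s.atoms:
        if a is m:
            continue
        if a.element.upper() not in donors_up:
            continue
        d = distance(a.coord, m.coord)
        if d <= cutoff:
            candidates.append((d, a))
    # one donor per imidazole: drop the farther of ND1/NE2 pairs
    his_best: dict[tuple[str, int], tuple[float, Atom]] = {}
    kept: list[tuple[float, Atom]] = []
    for d, a in candidates:
        if a.name in ("ND1", "NE2"):
            key = (a.chain, a.res_id)
            if key not in his_best or d < his_best[key][0]:
                his_best[key] = (d, a)
        else:
            kept.append((d, a))
    kept.extend(his_best.values())
    kept.sort(key=lambda t: t[0])
    ligands = [a for _, a in kept]
    distances = [d for d, _ in kept]
    lml = []
    for i in range(len(ligands)):
        for j in range(i + 1, len(ligands)):
            lml.append((i, j, angle(ligands[i].coord, m.coord, ligands[j].coord)))
    if not ligands:
        warnings.warn(
            f"no donor atoms within {cutoff} A of {m.element} {m.res_id}", stacklevel=2
        )
    return CoordinationSphere(metal=m, ligands=ligands, distances=distances, lml_angles=lml)


def addison_tau(sphere: CoordinationSphere) -> AddisonResult:
    """Addison tau of a 5-coordinate sphere.

    beta and alpha are the two largest ligand-metal-ligand angles;
    tau = (beta - alpha)/60.  Defined only for coordination number 5.
    """
    if sphere.coordination_number != 5:
        raise ValueError(
            f"Addison tau requires exactly 5 ligands, got {sphere.coordination_number}"
        )
    ordered = sorted(sphere.lml_angles, key=lambda t: t[2], reverse=True)
    (i1, j1, beta), (i2, j2, alpha) = ordered[0], ordered[1]
    tau = (beta - alpha) / 60.0
    involved = {i1, j1, i2, j2}
    apical = None
    leftover = [k for k in range(5) if k not in involved]
    if len(leftover) == 1:
        apical = sphere.ligands[leftover[0]]
    if tau <= 0.3:
        label = "square-pyramidal"
    elif tau >= 0.7:
        label = "trigonal-bipyramidal"
    else:
        label = "intermediate"
    return AddisonResult(tau=tau, beta=beta, alpha=alpha, apical_ligand=apical, label=label)


def jahn_teller_axis(sphere: CoordinationSphere) -> tuple[Atom, float, bool]:
    """Longest metal-ligand bond and its excess over the mean of the rest.

    Returns ``(ligand, elongation, significant)`` where ``elongation`` is
    the longest distance minus the mean of the remaining ones and
    ``significant`` is False when all bonds are effectively equal (excess
    below 0.05 Angstrom), i.e. no axial elongation is resolved.
    """
    if sphere.coordination_number < 4:
        raise ValueError("Jahn-Teller axis needs >= 4 ligands")
    d = np.asarray(sphere.distances)
    k = int(np.argmax(d))
    rest = np.delete(d, k)
    excess = float(d[k] - rest.mean())
    return sphere.ligands[k], excess, excess > 0.05


def chi_angles(s: Structure, res_id: int, chain: str | None = None) -> list[float]:
    """chi1..chi4 (degrees) of a lysine-like side chain.

    Uses the N-CA-CB-CG-CD-CE-NZ quadruples; a missing atom truncates the
    list at the last fully defined chi, so a side chain lacking CE yields
    only chi1 and chi2.
    """
    atoms: dict[str, Atom] = {}
    for a in s.atoms:
        if a.res_id == res_id and (chain is None or a.chain == chain):
            atoms.setdefault(a.name, a)
    if not atoms:
        raise KeyError(f"no residue {res_id}" + (f" in chain {chain}" if chain else ""))
    chis = []
    for quad in LYS_CHI_ATOMS:
        if not all(n in atoms for n in quad):
            break
        chis.append(dihedral(*(atoms[n].coord for n in quad)))
    return chis


def circular_deviation(a: float, b: float) -> float:
    """Smallest absolute angular difference |a-b| on the circle, degrees."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def classify_rotamer(chi: list[float] | tuple[float, ...]) -> RotamerState:
    """Map each chi to the nearest canonical rotamer letter.

    p = +65, t = 180, m = -65 under circular distance.  Every angle maps
    somewhere; ``max_deviation`` records the worst per-chi distance and a
    deviation above 40 degrees marks the state distorted.
    """
    letters = []
    devs = []
    for x in chi:
        best = min(
            CANONICAL_ROTAMERS.items(), key=lambda kv: circular_deviation(x, kv[1])
        )
        letters.append(best[0])
        devs.append(circular_deviation(x, best[1]))
    return RotamerState(
        chi=tuple(float(x) for x in chi),
        code="".join(letters),
        max_deviation=float(max(devs)) if devs else 0.0,
    )


def _ring_atoms(s: Structure, res_id: int, chain: str | None) -> np.ndarray:
    idx = s.residue_indices(res_id, chain)
    if not idx:
        raise KeyError(f"no residue {res_id}")
    res_name = s.atoms[idx[0]].res_name
    names = _AROMATIC_RING_ATOMS.get(res_name)
    if names is not None:
        coords = []
        by_name = {s.atoms[i].name: s.atoms[i] for i in idx}
        for n in names:
            if n in by_name:
                coords.append(by_name[n].coord)
        if len(coords) >= 5:
            return np.asarray(coords)
    # nonstandard ring (quinone cofactors): all ring-like carbons/nitrogens
    # named C1..C6 / N1..N3 style, falling back to every sp2-plausible atom
    coords = [
        s.atoms[i].coord
        for i in idx
        if s.atoms[i].element in ("C", "N") and s.atoms[i].name not in (
            "CA", "CB", "C", "N", "CD", "CE", "CG1", "CG2",
        )
    ]
    if len(coords) < 3:
        raise ValueError(f"residue {res_id} ({res_name}) has no recognisable ring")
    return np.asarray(coords)


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def pi_stacking(
    s: Structure,
    res_a: int,
    res_b: int,
    chain_a: str | None = None,
    chain_b: str | None = None,
    max_distance: float = 5.5,
    max_angle: float = 30.0,
) -> StackingContact:
    """Ring-ring stacking geometry between two aromatic residues.

    Centroid distance, interplanar angle between least-squares ring normals
    (folded to [0, 90]) and in-plane offset of the second centroid from the
    first ring's normal axis.  Stacked when distance <= ``max_distance``
    and angle <= ``max_angle``.
    """
    ring_a = _ring_atoms(s, res_a, chain_a)
    ring_b = _ring_atoms(s, res_b, chain_b)
    ca = ring_a.mean(axis=0)
    cb = ring_b.mean(axis=0)
    na = _plane_normal(ring_a)
    nb = _plane_normal(ring_b)
    cosang = abs(float(np.dot(na, nb)))
    inter = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    dvec = cb - ca
    d = float(np.linalg.norm(dvec))
    along = float(np.dot(dvec, na))
    offset = float(np.sqrt(max(d * d - along * along, 0.0)))
    return StackingContact(
        centroid_distance=d,
        interplanar_angle=inter,
        offset=offset,
        is_stacked=(d <= max_distance and inter <= max_angle),
    )


def vdw_contacts(
    s: Structure,
    res_a: int,
    res_b: int,
    tolerance: float = 0.5,
    chain_a: str | None = None,
    chain_b: str | None = None,
    include_hydrogens: bool = False,
) -> list[tuple[Atom, Atom, float]]:
    """Atom pairs of two residues with gap = d - (r_a + r_b) <= tolerance.

    Gaps use the fixed van der Waals radius table ``VDW_RADII``; pairs are
    sorted by gap so the tightest contact comes first.
    """
    ia = s.residue_indices(res_a, chain_a)
    ib = s.residue_indices(res_b, chain_b)
    if not ia or not ib:
        raise KeyError(f"residue {res_a if not ia else res_b} not found")
    out = []
    for i in ia:
        a = s.atoms[i]
        if not include_hydrogens and a.element == "H":
            continue
        ra = VDW_RADII.get(a.element.upper(), 1.7)
        for j in ib:
            b = s.atoms[j]
            if not include_hydrogens and b.element == "H":
                continue
            rb = VDW_RADII.get(b.element.upper(), 1.7)
            gap = distance(a.coord, b.coord) - (ra + rb)
            if gap <= tolerance:
                out.append((a, b, float(gap)))
    out.sort(key=lambda t: t[2])
    return out


def sidechain_separation_report(
    s: Structure, res_a: int, res_b: int, chain: str | None = None
) -> dict[str, float]:
    """Distances characterising the separation of two side chains.

    Reports named atom-pair distances where the atoms exist (e.g. Lys NZ to
    Tyr OH) plus the minimum over all side-chain heavy-atom pairs; useful
    for quantifying how far apart the two cofactor precursor residues sit.
    """
    backbone = {"N", "CA", "C", "O"}
    ia = [i for i in s.residue_indices(res_a, chain) if s.atoms[i].name not in backbone]
    ib = [i for i in s.residue_indices(res_b, chain) if s.atoms[i].name not in backbone]
    report: dict[str, float] = {}
    by_name_a = {s.atoms[i].name: s.atoms[i] for i in ia}
    by_name_b = {s.atoms[i].name: s.atoms[i] for i in ib}
    for na, nb in (("NZ", "OH"), ("NZ", "CZ"), ("NZ", "C2")):
        if na in by_name_a and nb in by_name_b:
            report[f"{na}-{nb}"] = distance(by_name_a[na].coord, by_name_b[nb].coord)
    pairs = [
        distance(s.atoms[i].coord, s.atoms[j].coord)
        for i in ia
        for j in ib
        if s.atoms[i].element != "H" and s.atoms[j].element != "H"
    ]
    if pairs:
        report["min_sidechain"] = float(min(pairs))
    return report
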