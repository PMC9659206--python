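"""Synthetic fixtures: metal sites with prescribed Addison tau, lysine side
chains with prescribed chi angles, Gaussian-fluctuation trajectories and
rotamer-switch schedules.

These generators define the conditions under which the analysis stages are
tested: 5-coordinate sites anywhere between the square-pyramidal and
trigonal-bipyramidal limits, side chains on any of the 81 {p,t,m}^4 rotamer
codes, trajectories with known per-residue fluctuation amplitudes saved at
a 40 ps frame spacing, and rotamer run schedules mirroring the
pttp -> mtmt -> pttp switching seen in the simulations this package
mirrors.  Every generator takes an explicit seed where randomness is
involved; there is no hidden global RNG state.

The Gaussian trajectory generator draws independent per-atom displacements:
it is a statistical surrogate for molecular dynamics (correct per-residue
fluctuation amplitudes), not a physical one (no inertia, no correlated
modes unless requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geomcore import place_atom, rotation_about_axis
from .siteanalysis import CANONICAL_ROTAMERS
from .structio import Atom, Structure, Trajectory

# ideal side-chain internal coordinates (Angstrom / degrees)
_CC = 1.53
_CN = 1.49
_N_CA = 1.46
_TET = 109.5


@dataclass
class HarmonicTrajSpec:
    """Recipe for a Gaussian-fluctuation trajectory.

    ``per_residue_sigma`` maps residue id to the per-coordinate fluctuation
    amplitude sigma (Angstrom); every atom of that residue fluctuates
    independently and isotropically with that sigma, so the expected Ca
    RMSF is sqrt(3) * sigma.  ``rigid_drift`` optionally superimposes a
    global rigid motion per frame, given as (degrees per frame about the
    z axis through the centroid, translation vector per frame in Angstrom);
    fitted statistics must be blind to it.
    """

    reference: Structure
    per_residue_sigma: dict[int, float]
    n_frames: int = 251
    seed: int = 0
    frame_spacing_ps: float = 40.0
    rigid_drift: tuple[float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(sig < 0 for sig in self.per_residue_sigma.values()):
            raise ValueError("sigma must be non-negative")


@dataclass
class RotamerSchedule:
    """Ordered (rotamer code, run length) blocks plus chi jitter (degrees)."""

    blocks: list[tuple[str, int]]
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for code, length in self.blocks:
            if length < 1:
                raise ValueError(f"run length must be >= 1, got {length}")
            if not all(c in CANONICAL_ROTAMERS for c in code):
                raise ValueError(f"rotamer code {code!r} not over {{p,t,m}}")

    @property
    def n_frames(self) -> int:
        return sum(length for _, length in self.blocks)

    def chi_for_frame(self, k: int) -> tuple[str, list[float]]:
        pos = 0
        for code, length in self.blocks:
            if k < pos + length:
                return code, [CANONICAL_ROTAMERS[c] for c in code]
            pos += length
        raise IndexError(k)


def _atom(serial, name, element, res_name, res_id, coord, chain="A", hetero=False):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_id=res_id,
        chain=chain,
        coord=np.asarray(coord, float),
        hetero=hetero,
    )


def make_ideal_metal_site(
    geometry: str = "square-pyramidal",
    bond_length: float = 2.1,
    tau_target: float | None = None,
    metal_element: str = "CU",
) -> Structure:
    """A bare metal site: metal at the origin, N donors at prescribed angles.

    ``geometry`` is one of ``square-pyramidal`` (tau = 0),
    ``trigonal-bipyramidal`` (tau = 1), ``tetrahedral`` (4-coordinate) or
    ``interpolated`` with ``tau_target`` in [0, 1].  The interpolated form
    keeps one basal trans angle at 180 deg and morphs the other to
    alpha = 180 - 60 * tau_target, so the realised Addison tau equals the
    request exactly.  Donors are nitrogen atoms on separate residues so
    sphere detection treats them independently.
    """
    r = bond_length
    if geometry == "square-pyramidal":
        dirs = [(0, 0, 1), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]
    elif geometry == "trigonal-bipyramidal":
        c, s = np.cos(np.radians(120)), np.sin(np.radians(120))
        dirs = [(0, 0, 1), (0, 0, -1), (1, 0, 0), (c, s, 0), (c, -s, 0)]
    elif geometry == "tetrahedral":
        dirs = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    elif geometry == "interpolated":
        if tau_target is None or not (0.0 <= tau_target <= 1.0):
            raise ValueError("interpolated geometry needs tau_target in [0, 1]")
        alpha = 180.0 - 60.0 * tau_target
        ha = np.radians(alpha / 2.0)
        dirs = [
            (0, 0, 1),                      # apical
            (1, 0, 0), (-1, 0, 0),          # trans pair, beta = 180
            (0, np.sin(ha), np.cos(ha)),    # pair at alpha
            (0, -np.sin(ha), np.cos(ha)),
        ]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    atoms = [_atom(1, metal_element.upper(), metal_element.upper(), metal_element.upper(), 1, (0, 0, 0), hetero=True)]
    for k, d in enumerate(dirs):
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        atoms.append(
            _atom(k + 2, "N", "N", "LIG", 10 + k, r * d, hetero=True)
        )
    return Structure(atoms=atoms, title=f"ideal {geometry} metal site")


def make_lys_sidechain(
    chi: tuple[float, float, float, float],
    attach_to: Structure | None = None,
    res_id: int = 653,
    chain: str = "A",
) -> Structure:
    """A lysine residue with exact requested chi1..chi4 torsions.

    Built with ideal internal coordinates (C-C 1.53 A, C-N 1.49 A,
    tetrahedral angles).  With ``attach_to``, the side chain is rebuilt on
    that structure's existing N/CA/CB frame of ``res_id`` (replacing any
    CG/CD/CE/NZ already present); otherwise a free-standing residue is
    returned.
    """
    chi = tuple(float(x) for x in chi)
    if len(chi) != 4 or not all(np.isfinite(chi)):
        raise ValueError("chi must be four finite angles")
    if attach_to is None:
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([_N_CA, 0.0, 0.0])
        # CB off the N-CA axis; its torsional placement is arbitrary
        theta = np.radians(180.0 - _TET)
        cb = ca + _CC * np.array([np.cos(theta), np.sin(theta), 0.0])
        base = Structure(
            atoms=[
                _atom(1, "N", "N", "LYS", res_id, n, chain),
                _atom(2, "CA", "C", "LYS", res_id, ca, chain),
                _atom(3, "CB", "C", "LYS", res_id, cb, chain),
            ]
        )
    else:
        base = attach_to.copy()
        keep = []
        for a in base.atoms:
            if a.res_id == res_id and a.chain == chain and a.name in ("CG", "CD", "CE", "NZ"):
                continue
            keep.append(a)
        if len(keep) != len(base.atoms):
            kept_ids = {id(a) for a in keep}
            remap = {}
            j = 0
            for i, a in enumerate(base.atoms):
                if id(a) in kept_ids:
                    remap[i] = j
                    j += 1
            base = Structure(
                atoms=keep,
                bonds={
                    (remap[i], remap[j2])
                    for i, j2 in base.bonds
                    if i in remap and j2 in remap
                },
                title=base.title,
            )
        n = base.atom(chain, res_id, "N").coord
        ca = base.atom(chain, res_id, "CA").coord
        cb = base.atom(chain, res_id, "CB").coord
    cg = place_atom(n, ca, cb, _CC, _TET, chi[0])
    cd = place_atom(ca, cb, cg, _CC, _TET, chi[1])
    ce = place_atom(cb, cg, cd, _CC, _TET, chi[2])
    nz = place_atom(cg, cd, ce, _CN, _TET, chi[3])
    start = max((a.serial for a in base.atoms), default=0)
    new = [
        _atom(start + 1, "CG", "C", "LYS", res_id, cg, chain),
        _atom(start + 2, "CD", "C", "LYS", res_id, cd, chain),
        _atom(start + 3, "CE", "C", "LYS", res_id, ce, chain),
        _atom(start + 4, "NZ", "N", "LYS", res_id, nz, chain),
    ]
    s = Structure(atoms=base.atoms + new, bonds=set(base.bonds), title=base.title or "lysine side-chain fixture")
    i_cb = s.index_of(chain, res_id, "CB")
    i_ca = s.index_of(chain, res_id, "CA")
    i_n = s.index_of(chain, res_id, "N")
    i_cg = s.index_of(chain, res_id, "CG")
    for pair in ((i_n, i_ca), (i_ca, i_cb), (i_cb, i_cg), (i_cg, i_cg + 1), (i_cg + 1, i_cg + 2), (i_cg + 2, i_cg + 3)):
        s.add_bond(*pair)
    return s


def make_harmonic_traj(spec: HarmonicTrajSpec) -> Trajectory:
    """Gaussian-fluctuation trajectory around a reference structure.

    Frame t = reference + iid N(0, sigma_res^2) per coordinate (+ optional
    global rigid drift).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference.coords
    sigma = np.zeros(len(spec.reference))
    for i, a in enumerate(spec.reference.atoms):
        sigma[i] = spec.per_residue_sigma.get(a.res_id, 0.0)
    frames = []
    centroid = ref.mean(axis=0)
    for t in range(spec.n_frames):
        noise = rng.standard_normal((len(sigma), 3)) * sigma[:, None]
        frame = ref + noise
        if spec.rigid_drift is not None:
            deg_per_frame, shift = spec.rigid_drift
            R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), deg_per_frame * t)
            frame = (frame - centroid) @ R.T + centroid + np.asarray(shift, float) * t
        frames.append(frame)
    return Trajectory(
        topology=spec.reference.copy(),
        frames=frames,
        frame_spacing_ps=spec.frame_spacing_ps,
    )


def make_rotamer_switch_traj(
    base: Structure,
    res_id: int,
    schedule: RotamerSchedule,
    chain: str = "A",
    frame_spacing_ps: float = 40.0,
) -> Trajectory:
    """Trajectory whose only motion is the scheduled side-chain rotamer.

    Each frame rebuilds CG/CD/CE/NZ of ``res_id`` from the (static) N/CA/CB
    frame at the scheduled chi angles plus Gaussian jitter; everything else
    is frozen.
    """
    for name in ("N", "CA", "CB", "CG", "CD", "CE", "NZ"):
        base.index_of(chain, res_id, name)  # raises KeyError if absent
    rng = np.random.default_rng(schedule.seed)
    n_at = base.atom(chain, res_id, "N").coord
    ca = base.atom(chain, res_id, "CA").coord
    cb = base.atom(chain, res_id, "CB").coord
    # preserve the base side chain's own bond lengths and angles
    from .geomcore import angle as _ang, distance as _dist

    names = ["CG", "CD", "CE", "NZ"]
    prev3 = [n_at, ca, cb]
    lengths = []
    angles = []
    chain_coords = [n_at, ca, cb]
    for nm in names:
        x = base.atom(chain, res_id, nm).coord
        lengths.append(_dist(chain_coords[-1], x))
        angles.append(_ang(chain_coords[-2], chain_coords[-1], x))
        chain_coords.append(x)
    idx = [base.index_of(chain, res_id, nm) for nm in names]
    ref = base.coords
    frames = []
    for k in range(schedule.n_frames):
        _, chis = schedule.chi_for_frame(k)
        if schedule.jitter > 0:
            chis = [c + rng.standard_normal() * schedule.jitter for c in chis]
        frame = ref.copy()
        a, b, c = prev3
        for nm_i, (L, A, chi_v) in enumerate(zip(lengths, angles, chis)):
            d = place_atom(a, b, c, L, A, chi_v)
            frame[idx[nm_i]] = d
            a, b, c = b, c, d
        frames.append(frame)
    return Trajectory(topology=base.copy(), frames=frames, frame_spacing_ps=frame_spacing_ps)


def make_toy_active_site() -> Structure:
    """A minimal mature-cofactor active-site fixture.

    Geometry (all by construction, metal at the origin):

    * Cu2+ with five donors: three imidazole-like NE2 nitrogens on short
      stalks (residues 626/628/630) and an equatorial water oxygen form the
      basal plane, with trans basal angles of 174 and 162 deg, so the
      Addison tau is (174 - 162) / 60 = 0.2 (distorted square pyramid);
    * a quinone-ring ligand (residue 689, "LTQ") whose oxo group O4 sits
      apical at 2.50 A while the basal donors sit at 2.05 A / 2.00 A, i.e.
      O4 marks the elongated (Jahn-Teller) axis;
    * a lysine arm (residue 653) crosslinked through NZ to ring atom C2;
    * a phenyl ring (residue 656, "PHE") stacked plane-parallel 3.5 A from
      the quinone ring;
    * a second, axial water placed trans to O4 at 2.80 A -- just outside
      the default 2.6 A donor cutoff, so the detected sphere stays
      5-coordinate.
    """
    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    serial = [0]

    def add(name, element, res_name, res_id, coord, hetero=False):
        serial[0] += 1
        atoms.append(_atom(serial[0], name, element, res_name, res_id, coord, hetero=hetero))
        return len(atoms) - 1

    i_cu = add("CU", "CU", "CU", 700, (0, 0, 0), hetero=True)

    r_n = 2.05
    beta_half = np.radians(174.0 / 2.0)   # His628-Cu-His630 trans angle
    alpha_half = np.radians(162.0 / 2.0)  # His626-Cu-Weq trans angle
    d628 = np.array([np.sin(beta_half), 0.0, -np.cos(beta_half)])
    d630 = np.array([-np.sin(beta_half), 0.0, -np.cos(beta_half)])
    d626 = np.array([0.0, np.sin(alpha_half), -np.cos(alpha_half)])
    d_weq = np.array([0.0, -np.sin(alpha_half), -np.cos(alpha_half)])

    for res_id, d in ((626, d626), (628, d628), (630, d630)):
        ne2 = r_n * d
        ce1 = ne2 + 1.35 * _unit(d + np.array([0.3, 0.3, 0.1]))
        cd2 = ne2 + 1.35 * _unit(d + np.array([-0.3, 0.3, -0.1]))
        i_n = add("NE2", "N", "HIS", res_id, ne2)
        i_c1 = add("CE1", "C", "HIS", res_id, ce1)
        i_c2 = add("CD2", "C", "HIS", res_id, cd2)
        bonds |= {(i_n, i_c1), (i_n, i_c2)}

    i_weq = add("O", "O", "HOH", 901, 2.00 * d_weq, hetero=True)
    i_wax = add("O", "O", "HOH", 902, (0.0, 0.0, -2.80), hetero=True)

    # quinone ring in the xz-plane above the metal; O4 apical at 2.50 A
    o4 = np.array([0.0, 0.0, 2.50])
    c4 = o4 + np.array([0.0, 0.0, 1.26])
    center = c4 + np.array([0.0, 0.0, 1.40])
    ring_idx = {}
    ring_names = ["C4", "C5", "C6", "C1", "C2", "C3"]
    for k, nm in enumerate(ring_names):
        ang = np.radians(-90.0 + 60.0 * k)
        pos = center + 1.40 * np.array([np.cos(ang), 0.0, np.sin(ang)])
        ring_idx[nm] = add(nm, "C", "LTQ", 689, pos, hetero=True)
    i_o4 = add("O4", "O", "LTQ", 689, o4, hetero=True)
    for a, b in zip(ring_names, ring_names[1:] + ring_names[:1]):
        bonds.add(tuple(sorted((ring_idx[a], ring_idx[b]))))
    bonds.add(tuple(sorted((ring_idx["C4"], i_o4))))

    # lysine arm crosslinked to ring C2, extending away from the ring
    c2 = atoms[ring_idx["C2"]].coord
    c1 = atoms[ring_idx["C1"]].coord
    c3 = atoms[ring_idx["C3"]].coord
    out_dir = _unit(c2 - center)
    nz = c2 + 1.40 * out_dir
    ce = place_atom(c1, c2, nz, _CN, 120.0, 180.0)
    cd = place_atom(c2, nz, ce, _CC, _TET, 180.0)
    # outward chain built NZ -> N at the pttp rotamer (chi4..chi1 = 65/180/180/65)
    cg = place_atom(nz, ce, cd, _CC, _TET, 65.0)
    cb = place_atom(ce, cd, cg, _CC, _TET, 180.0)
    ca = place_atom(cd, cg, cb, _CC, _TET, 180.0)
    n_bb = place_atom(cg, cb, ca, _N_CA, _TET, 65.0)
    lys = {}
    for nm, el, pos in (
        ("N", "N", n_bb), ("CA", "C", ca), ("CB", "C", cb), ("CG", "C", cg),
        ("CD", "C", cd), ("CE", "C", ce), ("NZ", "N", nz),
    ):
        lys[nm] = add(nm, el, "LYS", 653, pos)
    for a, b in (("N", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")):
        bonds.add(tuple(sorted((lys[a], lys[b]))))
    bonds.add(tuple(sorted((lys["NZ"], ring_idx["C2"]))))

    # stacked phenyl ring: parallel plane offset along the quinone normal (y)
    phe_center = center + np.array([0.0, 3.5, 0.0])
    phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    phe_idx = {}
    for k, nm in enumerate(phe_names):
        ang = np.radians(60.0 * k)
        pos = phe_center + 1.40 * np.array([np.cos(ang), 0.0, np.sin(ang)])
        phe_idx[nm] = add(nm, "C", "PHE", 656, pos)
    for a, b in zip(phe_names, phe_names[1:] + phe_names[:1]):
        bonds.add(tuple(sorted((phe_idx[a], phe_idx[b]))))

    return Structure(atoms=atoms, bonds=bonds, title="synthetic toy active site")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)
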