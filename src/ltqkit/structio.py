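"""Structure and trajectory I/O.

Every downstream stage consumes the three container types defined here:
:class:`Atom`, :class:`Structure` and :class:`Trajectory`.  PDB parsing and
writing is delegated to biotite (fixed-column ATOM/HETATM/MODEL records,
CONECT and residue-template bond perception); the plain-XYZ trajectory
dialect is implemented directly because synthetic trajectories should not
depend on any topology conventions.

Coordinates are in Angstrom throughout.  Residue numbering is taken from the
file and never silently changed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as _bst
import biotite.structure.io.pdb as _bpdb


class PDBParseError(ValueError):
    """Raised when a PDB or XYZ file cannot be interpreted."""


@dataclass
class Atom:
    """One atom of a structure.

    ``name`` follows PDB conventions ("NZ", "OH", "CA", ...), ``res_name``
    is the 3-letter residue name and may be nonstandard (e.g. "LTQ"),
    ``coord`` is a length-3 float array in Angstrom.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    hetero: bool = False
    ins_code: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


@dataclass
class Structure:
    """An ordered list of atoms plus an undirected bond graph.

    ``bonds`` stores unordered index pairs.  For standard residues the
    peptide connectivity can be perceived from residue templates on read;
    bonds created by patches (e.g. the Lys Nzeta - LTQ C2 crosslink) are
    explicit members of this set and survive PDB round-trips as CONECT
    records.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: set[tuple[int, int]] = field(default_factory=set)
    title: str = ""

    def __post_init__(self) -> None:
        self.bonds = {_norm_bond(i, j) for i, j in self.bonds}
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atom index")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.coord = xyz.copy()

    def copy(self) -> "Structure":
        return Structure(
            atoms=[a.copy() for a in self.atoms],
            bonds=set(self.bonds),
            title=self.title,
        )

    def index_of(self, chain: str, res_id: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.res_id == res_id and a.name == name:
                return i
        raise KeyError(f"no atom {name} in {chain}:{res_id}")

    def atom(self, chain: str, res_id: int, name: str) -> Atom:
        return self.atoms[self.index_of(chain, res_id, name)]

    def residue_indices(self, res_id: int, chain: str | None = None) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.res_id == res_id and (chain is None or a.chain == chain)
        ]

    def add_bond(self, i: int, j: int) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"bond ({i},{j}) references invalid atom index")
        self.bonds.add(_norm_bond(i, j))


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frame_spacing_ps`` carries the physical spacing between saved frames
    (40 ps in the simulations this package mirrors), so that frame counts
    translate into simulated time spans.
    """

    topology: Structure
    frames: list[np.ndarray] = field(default_factory=list)
    frame_spacing_ps: float = 40.0

    def __post_init__(self) -> None:
        if self.frame_spacing_ps <= 0:
            raise ValueError("frame_spacing_ps must be positive")
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k + 1}: {f.shape[0] if f.ndim else '?'} coordinates "
                    f"for a {n}-atom topology"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_span_ps(self) -> float:
        return self.n_frames * self.frame_spacing_ps

    def frame_structure(self, k: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[k])
        return s


def _norm_bond(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# biotite conversion


def _from_atom_array(arr: _bst.AtomArray, title: str = "") -> Structure:
    has_b = "b_factor" in arr.get_annotation_categories()
    has_occ = "occupancy" in arr.get_annotation_categories()
    has_serial = "atom_id" in arr.get_annotation_categories()
    has_ins = "ins_code" in arr.get_annotation_categories()
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                serial=int(arr.atom_id[i]) if has_serial else i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                res_name=str(arr.res_name[i]),
                res_id=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
                coord=np.array(arr.coord[i], dtype=float),
                occupancy=float(arr.occupancy[i]) if has_occ else 1.0,
                b_factor=float(arr.b_factor[i]) if has_b else 0.0,
                altloc="",
                hetero=bool(arr.hetero[i]),
                ins_code=str(arr.ins_code[i]) if has_ins else "",
            )
        )
    bonds: set[tuple[int, int]] = set()
    if arr.bonds is not None:
        for i, j, _ in arr.bonds.as_array():
            bonds.add(_norm_bond(int(i), int(j)))
    return Structure(atoms=atoms, bonds=bonds, title=title)


def _to_atom_array(s: Structure) -> _bst.AtomArray:
    n = len(s)
    arr = _bst.AtomArray(n)
    arr.coord = s.coords
    arr.atom_name = np.array([a.name for a in s.atoms], dtype="U6")
    arr.element = np.array([a.element for a in s.atoms], dtype="U2")
    arr.res_name = np.array([a.res_name for a in s.atoms], dtype="U5")
    arr.res_id = np.array([a.res_id for a in s.atoms], dtype=int)
    arr.chain_id = np.array([a.chain for a in s.atoms], dtype="U4")
    arr.hetero = np.array([a.hetero for a in s.atoms], dtype=bool)
    arr.ins_code = np.array([a.ins_code for a in s.atoms], dtype="U1")
    arr.set_annotation("b_factor", np.array([a.b_factor for a in s.atoms]))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in s.atoms]))
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms], dtype=int))
    return arr


# ---------------------------------------------------------------------------
# PDB


def read_pdb(
    path: str | Path,
    *,
    model: int | None = None,
    keep_altlocs: bool = False,
    infer_bonds: bool = True,
) -> Structure | list[Structure]:
    """Read a PDB file into one :class:`Structure` per model.

    A single-model file returns one Structure; a multi-model file returns a
    list unless ``model`` selects one (1-based, as in the file).  By default
    only the highest-occupancy altloc conformer of each atom is kept, so
    downstream geometry sees one position per atom; ``keep_altlocs=True``
    keeps all conformers, tagged via the ``altloc`` field.

    With ``infer_bonds`` (default) the bond set combines explicit CONECT
    records with residue-template connectivity for standard residues.

    Raises :class:`PDBParseError` on malformed records, naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_pdb_lines(path)
    try:
        f = _bpdb.PDBFile.read(str(path))
    except Exception as exc:  # biotite's errors carry the offending text
        raise PDBParseError(f"{path}: {exc}") from exc
    altloc = "all" if keep_altlocs else "occupancy"
    extra = ["b_factor", "occupancy", "atom_id"]
    if keep_altlocs:
        extra.append("altloc_id")
    try:
        stack = f.get_structure(
            model=model, altloc=altloc, extra_fields=extra, include_bonds=infer_bonds
        )
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    title = ""
    for line in f.lines:
        if line.startswith("TITLE"):
            title += line[10:].rstrip() + " "
    title = title.strip()

    def _one(arr: _bst.AtomArray) -> Structure:
        s = _from_atom_array(arr, title=title)
        if keep_altlocs and "altloc_id" in arr.get_annotation_categories():
            for a, al in zip(s.atoms, arr.altloc_id):
                a.altloc = "" if str(al) in (".", " ", "") else str(al)
        return s

    if isinstance(stack, _bst.AtomArray):
        return _one(stack)
    structures = [_one(stack[i]) for i in range(stack.stack_depth())]
    return structures[0] if len(structures) == 1 else structures


def _check_pdb_lines(path: Path) -> None:
    """Reject coordinate records whose mandatory fields do not parse."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}:{ln}: truncated coordinate record (missing coordinates)"
                    )
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"{path}:{ln}: unparseable coordinate fields: {line.rstrip()!r}"
                    ) from None


def write_pdb(
    s: Structure | Sequence[Structure], path: str | Path, *, conect: str = "explicit"
) -> None:
    """Write one structure (or several, as MODEL records) in PDB format.

    ``conect`` controls CONECT emission: "explicit" writes one record set
    for every bond stored in ``Structure.bonds`` (readers re-perceive
    standard-residue connectivity anyway, and patch-created crosslinks must
    survive), "none" suppresses them.
    """
    path = Path(path)
    multi = not isinstance(s, Structure)
    structures: list[Structure] = list(s) if multi else [s]
    if not structures or all(len(st) == 0 for st in structures):
        header = structures[0].title if structures else ""
        with open(path, "w") as fh:
            if header:
                fh.write(f"TITLE     {header[:70]}\n")
            fh.write("END\n")
        return
    for st in structures:
        for a in st.atoms:
            if len(a.name) > 4:
                raise ValueError(f"atom name {a.name!r} exceeds 4 characters")
            if a.res_id > 9999 or a.res_id < -999:
                raise ValueError(f"res_id {a.res_id} does not fit PDB columns")
    f = _bpdb.PDBFile()
    if multi:
        stack = _bst.stack([_to_atom_array(st) for st in structures])
        f.set_structure(stack)
    else:
        f.set_structure(_to_atom_array(structures[0]))
    lines = [ln for ln in f.lines if not ln.startswith("CONECT")]
    if conect == "explicit":
        conect_lines = _conect_records(structures[0])
        if lines and lines[-1].startswith("END"):
            lines = lines[:-1] + conect_lines + ["END"]
        else:
            lines = lines + conect_lines
    title = structures[0].title
    if title:
        lines = [f"TITLE     {title[:70]}"] + lines
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _conect_records(s: Structure) -> list[str]:
    neighbors: dict[int, list[int]] = {}
    for i, j in sorted(s.bonds):
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    lines = []
    for i in sorted(neighbors):
        serial = s.atoms[i].serial
        partners = [s.atoms[j].serial for j in sorted(neighbors[i])]
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            lines.append("CONECT" + f"{serial:>5}" + "".join(f"{p:>5}" for p in chunk))
    return lines


# ---------------------------------------------------------------------------
# trajectories


def read_traj(
    topology: Structure, path: str | Path, fmt: str = "auto"
) -> Trajectory:
    """Read a trajectory (multi-model PDB or plain XYZ) over ``topology``.

    Every frame must have exactly as many coordinates as the topology has
    atoms; a mismatch raises an error naming the offending frame (1-based).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "multi-model-pdb"
    if fmt == "xyz":
        frames, spacing = _read_xyz_frames(path)
    elif fmt in ("multi-model-pdb", "pdb"):
        models = read_pdb(path, infer_bonds=False)
        if isinstance(models, Structure):
            models = [models]
        frames = [m.coords for m in models]
        spacing = None
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    n = len(topology)
    for k, f in enumerate(frames):
        if f.shape[0] != n:
            raise PDBParseError(
                f"{path}: frame {k + 1} has {f.shape[0]} atoms, topology has {n}"
            )
    return Trajectory(
        topology=topology,
        frames=frames,
        frame_spacing_ps=spacing if spacing else 40.0,
    )


def _read_xyz_frames(path: Path) -> tuple[list[np.ndarray], float | None]:
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            nat = int(lines[pos].split()[0])
        except ValueError:
            raise PDBParseError(
                f"{path}: expected atom count at line {pos + 1}, got {lines[pos]!r}"
            ) from None
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        if "t=" in comment.replace(" ", ""):
            try:
                times.append(float(comment.replace(" ", "").split("t=")[1].split()[0].rstrip("ps")))
            except (ValueError, IndexError):
                pass
        block = lines[pos + 2 : pos + 2 + nat]
        if len(block) < nat:
            raise PDBParseError(
                f"{path}: frame {len(frames) + 1} truncated "
                f"({len(block)} of {nat} atom lines)"
            )
        coords = np.empty((nat, 3))
        for i, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBParseError(
                    f"{path}: bad XYZ atom line in frame {len(frames) + 1}: {ln!r}"
                )
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        pos += 2 + nat
    spacing = None
    if len(times) >= 2:
        spacing = times[1] - times[0]
    return frames, spacing


def write_traj(traj: Trajectory, path: str | Path, fmt: str = "auto") -> None:
    """Write a trajectory as multi-model PDB or plain XYZ.

    XYZ frames carry ``t= <ps> ps`` comment lines so spacing round-trips.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "multi-model-pdb"
    if fmt == "xyz":
        elements = [a.element or a.name[:1] for a in traj.topology.atoms]
        with open(path, "w") as fh:
            for k, frame in enumerate(traj.frames):
                fh.write(f"{len(elements)}\n")
                fh.write(f"t= {k * traj.frame_spacing_ps:.3f} ps\n")
                for el, (x, y, z) in zip(elements, frame):
                    fh.write(f"{el:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")
    elif fmt in ("multi-model-pdb", "pdb"):
        structures = [traj.frame_structure(k) for k in range(traj.n_frames)]
        write_pdb(structures, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# selection


def select(
    s: Structure,
    *,
    chain: str | None = None,
    res_id: int | Iterable[int] | None = None,
    res_range: tuple[int, int] | None = None,
    res_name: str | Iterable[str] | None = None,
    name: str | Iterable[str] | None = None,
    element: str | Iterable[str] | None = None,
    hetero: bool | None = None,
) -> list[int]:
    """Select atom indices by chain / residue id or range / names / element.

    Filters combine with AND; each filter accepts a scalar or an
    iterable of allowed values.  The result preserves the original atom
    order.  An empty selection warns rather than raising, because absent
    chains or residues are a data property, not a usage error.
    """

    def _as_set(v):
        if v is None:
            return None
        if isinstance(v, (str, int)):
            return {v}
        return set(v)

    res_ids = _as_set(res_id)
    res_names = _as_set(res_name)
    names = _as_set(name)
    elements = _as_set(element)
    out = []
    for i, a in enumerate(s.atoms):
        if chain is not None and a.chain != chain:
            continue
        if res_ids is not None and a.res_id not in res_ids:
            continue
        if res_range is not None and not (res_range[0] <= a.res_id <= res_range[1]):
            continue
        if res_names is not None and a.res_name not in res_names:
            continue
        if names is not None and a.name not in names:
            continue
        if elements is not None and a.element not in elements:
            continue
        if hetero is not None and a.hetero != hetero:
            continue
        out.append(i)
    if not out:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return out


_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "CU": 1.32, "ZN": 1.22, "FE": 1.32, "CL": 1.02,
}


def infer_bonds_by_distance(s: Structure, tolerance: float = 0.45) -> set[tuple[int, int]]:
    """Distance-based bond perception for nonstandard residues.

    Two atoms are bonded when their separation is below the sum of covalent
    radii plus ``tolerance`` (Angstrom).  Metals are excluded (coordination
    is not covalent bonding here).  Used as a fallback where neither CONECT
    nor residue templates provide connectivity.
    """
    coords = s.coords
    bonds: set[tuple[int, int]] = set()
    metals = {"CU", "ZN", "FE", "MN", "MG", "NA", "K", "CA"}
    for i in range(len(s)):
        ei = s.atoms[i].element.upper()
        if ei in metals:
            continue
        ri = _COVALENT_RADII.get(ei, 0.77)
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        for off in np.nonzero(d < 2.6)[0]:
            j = i + 1 + int(off)
            ej = s.atoms[j].element.upper()
            if ej in metals:
                continue
            rj = _COVALENT_RADII.get(ej, 0.77)
            if d[off] <= ri + rj + tolerance:
                bonds.add((i, j))
    return bonds
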