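"""Elementary vector geometry: distances, angles, dihedrals, least-squares
superposition and RMSD.

All angles are reported in degrees.  RMSD is in Angstrom by default with an
explicit nanometre toggle, because structure-overlay comparisons are
conventionally quoted in Angstrom while trajectory RMSD/RMSF plots use nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised for zero-length arms, collinear dihedral frames, or point sets
    with no unique rigid superposition."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body fit of a mobile point set onto a reference.

    ``rotation`` (3x3, proper: det = +1) and ``translation`` map mobile
    coordinates onto the reference frame as ``x @ rotation.T + translation``.
    A reflection is never returned; if the best orthogonal transform would
    be improper, the best proper rotation is used instead.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def distance(a, b) -> float:
    """Euclidean distance |a-b| in Angstrom."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.linalg.norm(a - b))


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("zero-length arm in angle()")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Torsion angle of the a-b-c-d chain, degrees in (-180, 180].

    IUPAC sign convention: looking from b towards c, a positive angle is a
    clockwise rotation of the far bond (c-d) relative to the near bond
    (b-a).  Reversing the atom order (d,c,b,a) returns the same value.
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear points in dihedral()")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def superpose(
    mobile: np.ndarray,
    ref: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Returns the proper rotation and translation minimising the (weighted)
    RMSD of ``mobile`` onto ``ref``.  Requires >= 3 points that are not all
    collinear; a reflection is guarded against by flipping the sign of the
    smallest singular direction.
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose needs two equal-shape (n,3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superpose needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mc = (wn[:, None] * mobile).sum(axis=0)
    rc = (wn[:, None] * ref).sum(axis=0)
    X = mobile - mc
    Y = ref - rc
    H = (wn[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    # collinear or coincident point sets leave the rotation underdetermined
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise DegenerateGeometryError("superpose: degenerate (collinear) point set")
    D = np.eye(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    msd = float((wn * ((fitted - ref) ** 2).sum(axis=1)).sum())
    return SuperpositionResult(rotation=R, translation=t, rmsd=float(np.sqrt(max(msd, 0.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place a new atom D from internal coordinates (NeRF construction).

    Given the three preceding atoms a-b-c, returns the position d with
    |c-d| = ``bond_length``, angle b-c-d = ``bond_angle`` (degrees) and
    dihedral a-b-c-d = ``torsion`` (degrees, IUPAC convention).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(bond_angle)
    phi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("place_atom: a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(phi),
            bond_length * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a (normalised) axis, degrees."""
    u = np.asarray(axis, float)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise DegenerateGeometryError("rotation axis has zero length")
    u = u / nu
    t = np.radians(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return ct * np.eye(3) + st * K + (1 - ct) * np.outer(u, u)


def rmsd(
    A: np.ndarray,
    B: np.ndarray,
    fit: bool = True,
    weights: np.ndarray | None = None,
    unit: str = "angstrom",
) -> float:
    """Root-mean-square deviation between two coordinate sets.

    ``fit=True`` first finds the optimal rigid superposition of A onto B,
    giving the minimum over all rigid motions; ``fit=False`` compares the
    coordinates as given.  ``unit`` is "angstrom" (default) or "nm".
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("rmsd needs equal-shape coordinate sets")
    if fit:
        value = superpose(A, B, weights=weights).rmsd
    else:
        if weights is None:
            value = float(np.sqrt(((A - B) ** 2).sum(axis=1).mean()))
        else:
            w = np.asarray(weights, float)
            wn = w / w.sum()
            value = float(np.sqrt((wn * ((A - B) ** 2).sum(axis=1)).sum()))
    if unit == "nm":
        return value / 10.0
    if unit in ("angstrom", "A", "Å"):
        return value
    raise ValueError(f"unknown unit {unit!r}")
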