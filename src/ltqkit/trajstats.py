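"""Trajectory-level analyses: fitted RMSD series, RMSF, B-factor
conversion, Ca covariance PCA, displacement-vector fields, and per-frame
Addison-tau / rotamer time series.

Conventions: frames are indexed from 1 in all reported run boundaries
(matching how simulation frame ranges are quoted) and 0-based internally;
RMSD/RMSF are reported in nm by default (the customary unit for these
plots) while B-factors and displacement fields are in Angstrom^2 and
Angstrom.  All fitted statistics are invariant under a global rigid motion
applied to any frame, because every frame is least-squares superposed
before measuring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geomcore import superpose
from .siteanalysis import (
    DEFAULT_COORDINATION_CUTOFF,
    AddisonResult,
    RotamerState,
    addison_tau,
    chi_angles,
    classify_rotamer,
    find_coordination_sphere,
)
from .structio import Structure, Trajectory, select

#: Debye-Waller conversion constant: B = (8 pi^2 / 3) * RMSF^2 (RMSF in A).
B_FACTOR_CONSTANT = 8.0 * np.pi**2 / 3.0


@dataclass
class RMSDSeries:
    values: np.ndarray  # per-frame, in `unit`
    unit: str
    reference_frame: int  # 1-based
    plateau_window: tuple[int, int] | None  # 1-based inclusive frame range
    plateau_mean: float | None
    plateau_sd: float | None


@dataclass
class RMSFProfile:
    """Per-atom root-mean-square fluctuation about the iterated mean
    structure, plus its summary statistics (all in ``unit``)."""

    values: np.ndarray
    atom_indices: list[int]
    unit: str
    max: float = field(init=False)
    min: float = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(v < 0):
            raise ValueError("RMSF values must be non-negative")
        self.max = float(v.max())
        self.min = float(v.min())
        self.mean = float(v.mean())
        self.sd = float(v.std())


@dataclass
class PCAResult:
    """Eigendecomposition of the 3N x 3N covariance of superposed
    coordinates: eigenvalues descending (unit^2), per-mode variance
    fractions, orthonormal 3N eigenvectors (rows of ``eigenvectors``) and
    per-frame projections on the leading modes."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    unit: str

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class DisplacementField:
    res_ids: list[int]
    vectors: np.ndarray  # (n_residues, 3), Angstrom
    threshold: float
    exceeding: list[int] = field(init=False)

    def __post_init__(self) -> None:
        mags = np.linalg.norm(self.vectors, axis=1)
        self.exceeding = [
            rid for rid, m in zip(self.res_ids, mags) if m > self.threshold
        ]


@dataclass
class TauSeries:
    """Per-frame Addison results (None where the coordination number was
    not 5) and summary statistics over the defined frames."""

    results: list[AddisonResult | None]
    mean: float | None
    sd: float | None
    sem: float | None
    max: float | None
    n_undefined: int

    @property
    def taus(self) -> list[float | None]:
        return [r.tau if r is not None else None for r in self.results]


@dataclass
class RotamerSeries:
    states: list[RotamerState]
    runs: list[tuple[str, int, int]]  # (code or "mobile", first, last), 1-based

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.states]


def _ca_selection(traj: Trajectory) -> list[int]:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = select(traj.topology, name="CA", element="C")
    if len(sel) < 3:  # superposition needs a proper frame; fall back to all
        sel = list(range(len(traj.topology)))
    return sel


def _fit_frames(
    traj: Trajectory, selection: list[int] | None, iterations: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto the iterated mean structure.

    Starting from frame 0 as reference, each round fits every frame onto
    the current mean of the selected atoms and recomputes the mean; two
    rounds make the reference self-consistent.  Returns the fitted selected
    coordinates (n_frames, n_sel, 3) and the final mean (n_sel, 3).
    """
    sel = selection if selection is not None else _ca_selection(traj)
    X = np.array([f[sel] for f in traj.frames], dtype=float)
    mean = X[0].copy()
    for _ in range(iterations):
        for k in range(X.shape[0]):
            fit = superpose(X[k], mean)
            X[k] = fit.apply(X[k])
        mean = X.mean(axis=0)
    return X, mean


def rmsd_series(
    traj: Trajectory,
    selection: list[int] | None = None,
    reference_frame: int = 1,
    unit: str = "nm",
    plateau_window: tuple[int, int] | None = None,
) -> RMSDSeries:
    """Per-frame RMSD to a reference frame after superposition.

    ``reference_frame`` and ``plateau_window`` are 1-based frame numbers;
    the plateau summary (mean +/- SD over the stated window) quantifies how
    far the stabilised trajectory sits from the starting conformation.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    sel = selection if selection is not None else _ca_selection(traj)
    if not sel:
        raise ValueError("empty selection")
    ref = traj.frames[reference_frame - 1][sel]
    scale = 0.1 if unit == "nm" else 1.0
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        values[k] = superpose(frame[sel], ref).rmsd * scale
    mean = sd = None
    if plateau_window is not None:
        lo, hi = plateau_window
        window = values[lo - 1 : hi]
        mean = float(window.mean())
        sd = float(window.std())
    return RMSDSeries(
        values=values,
        unit=unit,
        reference_frame=reference_frame,
        plateau_window=plateau_window,
        plateau_mean=mean,
        plateau_sd=sd,
    )


def rmsf_profile(
    traj: Trajectory, selection: list[int] | None = None, unit: str = "nm"
) -> RMSFProfile:
    """Per-atom RMSF about the iterated mean structure (2 fitting rounds).

    RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames, after superposing every
    frame onto the mean of the selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = selection if selection is not None else _ca_selection(traj)
    X, mean = _fit_frames(traj, sel)
    dev = X - mean
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    scale = 0.1 if unit == "nm" else 1.0
    return RMSFProfile(values=rmsf * scale, atom_indices=list(sel), unit=unit)


def bfactor_from_rmsf(profile: RMSFProfile) -> np.ndarray:
    """Convert an RMSF profile to Debye-Waller B-factors (Angstrom^2).

    B = (8 pi^2 / 3) * RMSF^2 with RMSF in Angstrom.
    """
    values = profile.values
    if profile.unit == "nm":
        values = values * 10.0
    return B_FACTOR_CONSTANT * values**2


def pca_ca(
    traj: Trajectory,
    selection: list[int] | None = None,
    n_components: int = 10,
    unit: str = "nm",
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> PCAResult:
    """PCA of the covariance matrix of superposed Ca coordinates.

    Frames are superposed to the iterated mean (same fit as the RMSF
    profile, so the eigenvalue sum equals the summed squared RMSF), the
    3N x 3N population covariance is diagonalised, eigenvalues are sorted
    descending and fractions are lambda_k over the total.  Projections are
    the centred frame coordinates on the leading ``n_components``
    eigenvectors.  ``mass_weighted`` rescales coordinates by sqrt(m_i)
    first (off by default; plain coordinate covariance).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = selection if selection is not None else _ca_selection(traj)
    X, mean = _fit_frames(traj, sel)
    scale = 0.1 if unit == "nm" else 1.0
    flat = (X - mean).reshape(traj.n_frames, -1) * scale
    if mass_weighted:
        if masses is None:
            masses = np.array(
                [12.011 if traj.topology.atoms[i].element == "C" else 14.0 for i in sel]
            )
        w = np.sqrt(np.repeat(masses, 3))
        flat = flat * w
    cov = flat.T @ flat / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    k = min(n_components, evals.size)
    projections = flat @ evecs[:, :k]
    return PCAResult(
        eigenvalues=evals,
        variance_fractions=fractions,
        eigenvectors=evecs.T,
        projections=projections,
        unit=unit,
    )


def displacement_field(
    traj: Trajectory,
    first_frame: int = 1,
    last_frame: int | None = None,
    threshold: float = 3.0,
    selection: list[int] | None = None,
) -> DisplacementField:
    """Per-residue Ca displacement vectors between two frames.

    The last frame is superposed onto the first on the Ca selection, then
    each residue's Ca displacement vector (Angstrom) is reported; residues
    whose displacement magnitude exceeds ``threshold`` form the exceeding
    set (3 A and 2.5 A are typical choices for highlighting moving loops).
    """
    if last_frame is None:
        last_frame = traj.n_frames
    sel = selection if selection is not None else _ca_selection(traj)
    a = traj.frames[first_frame - 1][sel]
    b = traj.frames[last_frame - 1][sel]
    fit = superpose(b, a)
    vectors = fit.apply(b) - a
    res_ids = [traj.topology.atoms[i].res_id for i in sel]
    return DisplacementField(res_ids=res_ids, vectors=vectors, threshold=threshold)


def tau_series(
    traj: Trajectory,
    metal_index: int | None = None,
    metal_element: str = "CU",
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
) -> TauSeries:
    """Addison tau at every frame.

    Frames whose detected coordination number is not 5 are reported as
    undefined (None) and counted, not silently dropped; mean/SD/SEM/max are
    over the defined frames only.
    """
    if metal_index is None:
        hits = [
            i
            for i, a in enumerate(traj.topology.atoms)
            if a.element.upper() == metal_element.upper()
        ]
        if len(hits) != 1:
            raise ValueError(
                f"{len(hits)} {metal_element} atoms in topology; give metal_index"
            )
        metal_index = hits[0]
    results: list[AddisonResult | None] = []
    for k in range(traj.n_frames):
        s = traj.frame_structure(k)
        sphere = find_coordination_sphere(s, s.atoms[metal_index], cutoff=cutoff)
        if sphere.coordination_number != 5:
            results.append(None)
        else:
            results.append(addison_tau(sphere))
    taus = np.array([r.tau for r in results if r is not None])
    n_undef = sum(1 for r in results if r is None)
    if taus.size:
        return TauSeries(
            results=results,
            mean=float(taus.mean()),
            sd=float(taus.std()),
            sem=float(taus.std() / np.sqrt(taus.size)),
            max=float(taus.max()),
            n_undefined=n_undef,
        )
    return TauSeries(results=results, mean=None, sd=None, sem=None, max=None, n_undefined=n_undef)


def rotamer_series(
    traj: Trajectory,
    res_id: int,
    chain: str | None = None,
    min_run: int = 5,
) -> RotamerSeries:
    """Per-frame rotamer codes of a lysine-like side chain, with maximal
    runs segmented.

    Contiguous frames sharing a code form a run, reported as (code,
    first_frame, last_frame) with 1-based inclusive frame numbers.  Runs
    shorter than ``min_run`` frames are rapid flips between stable states
    and are merged into "mobile" stretches rather than reported as
    individual rotamers.
    """
    states = []
    for k in range(traj.n_frames):
        s = traj.frame_structure(k)
        states.append(classify_rotamer(chi_angles(s, res_id, chain)))
    codes = [st.code for st in states]
    raw: list[tuple[str, int, int]] = []
    start = 0
    for k in range(1, len(codes) + 1):
        if k == len(codes) or codes[k] != codes[start]:
            raw.append((codes[start], start + 1, k))
            start = k
    runs: list[tuple[str, int, int]] = []
    for code, lo, hi in raw:
        if hi - lo + 1 < min_run:
            if runs and runs[-1][0] == "mobile":
                runs[-1] = ("mobile", runs[-1][1], hi)
            else:
                runs.append(("mobile", lo, hi))
        else:
            runs.append((code, lo, hi))
    return RotamerSeries(states=states, runs=runs)
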