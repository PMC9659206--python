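# Methods

This note records the models, conventions, numerical choices and known
limitations behind `ltqkit`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry kernel

Angles and torsions are reported in degrees everywhere. Torsions follow
the IUPAC sign convention (looking along the central bond, a positive
angle is a clockwise rotation of the far bond relative to the near one),
computed with the atan2 form that is stable near 0°/180°; values lie in
(−180°, 180°]. Degenerate inputs (zero-length arms, collinear torsion
frames) raise `DegenerateGeometryError` rather than returning NaN.

Rigid superposition uses the SVD (Kabsch) solution with a reflection
guard: if the best orthogonal transform is improper, the smallest
singular direction is flipped so a proper rotation (det = +1) is always
returned; point sets whose second singular value vanishes (collinear)
are rejected. The test suite cross-checks the result against an
independently implemented quaternion (Kearsley) eigen-solution to
1e−9 Å. RMSD is reported in Å by default with an `unit="nm"` toggle,
because overlay comparisons between static structures are quoted in Å
while trajectory RMSD/RMSF plots conventionally use nm.

## Structure I/O

PDB parsing and writing is delegated to biotite behind small dataclass
containers (`Atom`, `Structure`, `Trajectory`). Residue numbering is
taken from the file and never silently changed. Altloc handling keeps
the highest-occupancy conformer by default (downstream geometry needs
one position per atom); `keep_altlocs=True` retains all conformers.
Bonds combine explicit CONECT records with biotite's residue-template
perception; our writer emits CONECT for every bond stored in
`Structure.bonds`, so patch-created crosslinks (e.g. Lys Nζ–ring C2)
survive round trips. A distance-based fallback (covalent radii + 0.45 Å,
metals excluded) covers nonstandard residues with no template.

The XYZ trajectory dialect is one `element x y z` line per atom with the
frame time on the comment line (`t= <ps> ps`), chosen so synthetic
trajectories are dependency- and topology-free. Frame spacing defaults
to 40 ps — the save interval of the production simulations this package
mirrors — so frame counts translate directly into simulated time spans.

## Remodelling

**Dihedral transplantation** is implemented as graph-based torsion
driving rather than a full internal-coordinate re-extension: for each
backbone torsion (ω, then φ, then ψ per residue), the connected
component on the moving side of the rotated bond is turned rigidly about
that bond to the requested angle. Consequences, all exact rather than
approximate: only torsions change (bond lengths and angles are
bitwise-preserved), atoms on the anchor side never move, and atoms
distal to the segment are carried rigidly. The default anchor is
upstream (N-terminal side fixed), matching the remodelling of a short
internal strand while the rest of the fold stays put; `downstream`
mirrors this. A peptide C–N distance > 2.5 Å inside the segment is a
chain break and an error. Template ω values within 30° of trans are
snapped to exactly 180° (`clamp_omega=True`), so noisy templates cannot
introduce accidental cis peptides; a genuinely cis template ω is kept.
Torsions through ring bonds are refused (the moving set would contain
the defining atoms).

**Cofactor patches** are declarative: atom deletions, internal-coordinate
atom additions (three reference atoms + bond length/angle/torsion), bond
edits and residue renames. Deleting an atom that still carries a bond
not scheduled for deletion is an error naming the bond; atom and bond
counts therefore change exactly by the patch sizes. `invert_patch`
reconstructs deleted atoms from internal coordinates measured in the
original structure, choosing the nearest non-degenerate reference frame,
so apply∘invert restores the original graph and coordinates. The
built-in crosslink patch removes the quinone C2 oxygen and bonds the
lysine Nζ to ring C2 with a recorded target length of 1.40 Å (aromatic
C–N) prior to any external relaxation; the adduct-removal patch deletes
the 2-hydrazinopyridine-derived atoms and restores a carbonyl oxygen at
C5 (1.23 Å, trigonal, in-plane).

**Coordination waters.** Given a metal and ≥ 3 basal donors, the
equatorial water oxygen is placed along the in-plane direction opposite
the vector sum of the donor directions (the basal gap), and the axial
water along the normal of the donor least-squares plane (orientable via
`axial_direction`). Defaults Cu–O<sub>eq</sub> = 2.00 Å and
Cu–O<sub>ax</sub> = 2.40 Å: in a d⁹ Cu²⁺ site the axial bond is the
Jahn–Teller-elongated direction, 0.2–0.4 Å longer than the basal bonds.
Donor sets with no resolvable gap (already balanced) are an error.
Optional hydrogens are placed at 0.96 Å with metal–O–H angles of exactly
120°, the orientation that the charge-repulsion surrogate restraint
targets.

**Restraint evaluators.** Energy minimisation is deliberately not
re-implemented (it is an external engine's job); the two restraint kinds
used around the metal are provided as geometric evaluators so any
minimiser's output can be checked: a four-atom planarity improper
(deviation = |improper dihedral|, folded so 180° counts as planar) and a
target angle (deviation = |angle − target|), with quadratic penalty
weight·deviation².

## Site analysis

**Coordination sphere.** First-shell donors are N/O/S atoms within a
cutoff, default 2.6 Å — wide enough for the long axial Cu–O bond of an
elongated site (~2.5 Å) and typical 2.0–2.2 Å M–N bonds, while excluding
second-shell imidazoles at ≥ 3 Å. When both imidazole nitrogens of one
histidine fall inside the cutoff only the nearer one is counted (the
tautomer is rarely known). An empty shell warns rather than raising.

**Addison τ.** For exactly five ligands, β ≥ α are the two largest
ligand–metal–ligand angles and τ = (β − α)/60: 0 for the ideal square
pyramid, 1 for the ideal trigonal bipyramid. The apical ligand is the
donor appearing in neither β nor α. The qualitative labels (τ ≤ 0.3
square-pyramidal-like, τ ≥ 0.7 trigonal-bipyramidal-like) are reporting
conventions of this package; the numeric τ is always reported. τ is
invariant under rigid motions and ligand relabelling (tested).

**Jahn–Teller axis** is detected as the longest metal–ligand bond; the
elongation is its excess over the mean of the remaining bonds, with
excesses below 0.05 Å flagged as "no elongation resolved".

**Rotamers.** χ₁–χ₄ use the lysine quadruples N–Cα–Cβ–Cγ through
Cγ–Cδ–Cε–Nζ (shared by the native and LTQ-crosslinked side chain); a
missing atom truncates the list. Classification maps each χ to the
nearest of p = +65°, t = 180°, m = −65° under circular distance —
nearest-canonical bins rather than the full per-position rotamer-library
means, because those three letters at those values are the convention
the analyses report in. The worst per-χ deviation is recorded and a
deviation > 40° marks the state "distorted". The canonical letters are
separated by ≥ 115°, so any jitter ≤ 20° classifies identically
(exercised over all 81 codes).

**Stacking / contacts.** Ring planes are least-squares fits (standard
ring atom sets for Phe/Tyr/Trp/His; ring-plausible C/N atoms for quinone
cofactors). A contact is "stacked" when centroid distance ≤ 5.5 Å and
interplanar angle ≤ 30°. Van der Waals gaps use a fixed Bondi-type
radius table recorded in `siteanalysis.VDW_RADII` with default tolerance
0.5 Å.

## Trajectory statistics

All fitted statistics superpose each frame before measuring and are
therefore invariant under arbitrary per-frame rigid motions (tested to
1e−9). The superposition reference for RMSF and PCA is the iterated mean
structure (two fitting rounds starting from frame 1), computed on the
same selection, so the two share one set of fitted coordinates; this
makes the identity Σλₖ = Σᵢ RMSFᵢ² exact to rounding. The RMSD series
reference is the first frame by default, with a user-specified plateau
window for the mean ± SD summary. Frames are 1-based in all reports
(matching how simulation frame ranges are quoted) and 0-based
internally.

B-factors use the standard Debye–Waller form B = (8π²/3)·RMSF² with
RMSF in Å (26.319 Å² at RMSF = 1 Å); being a monotone transform, the
peak set equals the RMSF peak set. PCA diagonalises the population
covariance of the flattened 3N coordinates; eigenvalues are clipped at
zero, sorted descending, fractions are λₖ/Σλ, and projections are the
centred frames on the leading eigenvectors. Mass weighting is off by
default (plain coordinate covariance) with a flag, since conventions
differ between tools.

Per-frame τ series report frames whose detected coordination number is
not 5 as undefined — counted and listed, excluded from mean/SD/SEM/max —
rather than silently dropped; the summary reports mean, SD, SEM and max,
all labelled, since "±" conventions vary. Rotamer series segment
per-frame codes into maximal runs; runs shorter than a configurable
minimum (default 5 frames) are merged into "mobile" stretches, because
single-frame flips between stable states are noise at 40 ps sampling.

## Synthetic generators

Generators are the package's study conditions: deterministic per seed
(mandatory argument; no global RNG state), bitwise-reproducible.

- `make_ideal_metal_site` places donors at prescribed angles; the
  `interpolated` form keeps one basal trans angle at 180° and sets the
  other to α = 180° − 60τ, so the realised τ equals the request exactly
  (recovered to 1e−6 over a τ ∈ {0, 0.1, …, 1.0} grid).
- `make_lys_sidechain` builds ideal internal coordinates (C–C 1.53 Å,
  C–N 1.49 Å, tetrahedral angles) at exact requested torsions.
- `make_harmonic_traj` draws iid Gaussian displacements per atom with
  per-residue amplitudes σ (Å per coordinate; expected RMSF = √3·σ),
  optionally under a global rigid drift that fitted statistics must
  ignore. This is a statistical surrogate for MD — correct per-residue
  fluctuation amplitudes and sampling noise — not a physical one: no
  inertia, no solvent, no correlated modes (a collective mode can be
  added explicitly where a dominant-mode spectrum is needed). Passing
  tests therefore demonstrate correctness of the statistics, not
  realism of protein dynamics.
- `make_rotamer_switch_traj` rebuilds only the four side-chain torsion
  atoms per frame at scheduled χ plus jitter, keeping the base bond
  lengths/angles; the backbone is static by construction.
- `make_toy_active_site` is a documented 32-atom fixture: basal trans
  angles 174°/162° give τ = 0.2 by construction; the quinone O4 sits
  apical at 2.50 Å versus 2.00–2.05 Å basal bonds (Jahn–Teller axis);
  the second water sits trans-axial at 2.80 Å, deliberately outside the
  2.6 Å cutoff so the detected sphere stays 5-coordinate; the lysine arm
  is crosslinked at the pttp rotamer; a phenyl ring is stacked
  plane-parallel at 3.5 Å.

### Finite-size note on amplitude recovery

Least-squares fitting removes six rigid degrees of freedom per frame,
which perturbs per-atom apparent variance by O(1/N): large-amplitude
atoms are damped and small-amplitude atoms inherit cross-talk from the
fit jitter. At N = 32 atoms this bias reaches ~15% of a small residue's
RMSF; at protein size it is ~1%. The amplitude-recovery check
(σᵢ from RMSFᵢ/√3, ≤ 10% relative error at 1000 frames) is therefore
run on a 100-residue (300-atom) ideal backbone — the size regime the
statistic is used in — where measured recovery error is 3–7% across
seeds.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with comfortable statistics: 11-point τ grids, all 81 rotamer
codes, 180-frame rotamer schedules, 251-frame trajectories for
invariance checks, 1000 frames × 300 atoms for amplitude recovery, and
100–120 frame trajectories for PCA. The full suite runs in seconds.

## Known limitations

- No energy model: clashes introduced by grafting or patching are not
  detected; the restraint evaluators check only the two geometric
  restraint kinds.
- Torsion driving cannot cross ring bonds (flexible-ring remodelling is
  out of scope).
- Rotamer analysis covers χ-chain side chains of the lysine topology;
  other residue types get χ extraction only as far as the small built-in
  definition table goes.
- The coordination-sphere donor rule is purely distance-based; no
  bond-valence or electronic-structure reasoning.
- mmCIF writing and binary trajectory formats are not implemented
  (multi-model PDB and XYZ cover the tested paths; adapters can wrap
  external readers since a `Trajectory` is just frames over a topology).
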