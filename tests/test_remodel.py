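"""Remodelling: dihedral extraction/transplantation, grafting, patches,
metal swap, water placement, restraint evaluation."""

import numpy as np
import pytest

from ltqkit.geomcore import angle, distance, rotation_about_axis
from ltqkit.remodel import (
    ChainBreakError,
    PatchError,
    RestraintSpec,
    apply_patch,
    evaluate_restraints,
    extract_segment_dihedrals,
    graft_sidechain_template,
    invert_patch,
    make_ltq2hp_crosslink_patch,
    make_ltq2hp_to_ltq_patch,
    parse_patch_file,
    place_coordination_waters,
    swap_metal,
    transplant_segment_dihedrals,
)
from ltqkit.siteanalysis import addison_tau, find_coordination_sphere
from ltqkit.structio import Atom, Structure
from ltqkit.synthgen import make_ideal_metal_site, make_toy_active_site
from conftest import build_peptide, build_random_torsion_peptide


# ---------------------------------------------------------------------------
# extraction


@pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 120.0)])
def test_extraction_recovers_construction_angles(phi, psi):
    pep = build_peptide(6, phi, psi)
    seg = extract_segment_dihedrals(pep, "A", (1, 6))
    for rec in seg.residues:
        if rec.phi is not None:
            assert rec.phi == pytest.approx(phi, abs=1e-6)
        if rec.psi is not None:
            assert rec.psi == pytest.approx(psi, abs=1e-6)
        if rec.omega is not None:
            assert abs(rec.omega) == pytest.approx(180.0, abs=1e-6)


def test_terminal_angles_absent():
    pep = build_peptide(2, -57.0, -47.0)
    seg = extract_segment_dihedrals(pep, "A", (1, 2))
    assert seg.residues[0].phi is None
    assert seg.residues[0].omega is None
    assert seg.residues[-1].psi is None


def test_missing_backbone_atom_names_residue():
    pep = build_peptide(4, -57.0, -47.0)
    broken = Structure(
        atoms=[a for a in pep.atoms if not (a.res_id == 3 and a.name == "CA")]
    )
    with pytest.raises(ValueError, match="3"):
        extract_segment_dihedrals(broken, "A", (1, 4))


# ---------------------------------------------------------------------------
# transplantation


@pytest.mark.parametrize(
    "builder",
    [
        lambda: build_peptide(6, -57.0, -47.0),
        lambda: build_peptide(6, -120.0, 120.0),
        lambda: build_random_torsion_peptide(6, seed=3),
    ],
    ids=["helix", "strand", "random-torsions"],
)
def test_identity_transplant_is_noop(builder):
    pep = builder()
    seg = extract_segment_dihedrals(pep, "A", (1, 6))
    out = transplant_segment_dihedrals(pep, "A", (2, 5), seg, clamp_omega=False)
    assert np.abs(out.coords - pep.coords).max() < 1e-6


def test_transplant_realises_requested_angles():
    ext = build_peptide(6, -120.0, 120.0)
    helix = build_peptide(6, -57.0, -47.0)
    seg = extract_segment_dihedrals(helix, "A", (1, 6))
    out = transplant_segment_dihedrals(ext, "A", (1, 6), seg)
    got = extract_segment_dihedrals(out, "A", (1, 6))
    for rec, want in zip(got.residues, seg.residues):
        if want.phi is not None:
            assert rec.phi == pytest.approx(want.phi, abs=1e-4)
        if want.psi is not None:
            assert rec.psi == pytest.approx(want.psi, abs=1e-4)


def test_transplant_preserves_bond_lengths_and_angles():
    ext = build_peptide(6, -120.0, 120.0)
    helix = build_peptide(6, -57.0, -47.0)
    seg = extract_segment_dihedrals(helix, "A", (1, 6))
    out = transplant_segment_dihedrals(ext, "A", (1, 6), seg)
    for i, j in ext.bonds:
        assert distance(out.atoms[i].coord, out.atoms[j].coord) == pytest.approx(
            distance(ext.atoms[i].coord, ext.atoms[j].coord), abs=1e-6
        )
    # consecutive-bond angles along the chain
    coords_a = ext.coords
    coords_b = out.coords
    for k in range(1, len(ext) - 1):
        assert angle(coords_b[k - 1], coords_b[k], coords_b[k + 1]) == pytest.approx(
            angle(coords_a[k - 1], coords_a[k], coords_a[k + 1]), abs=1e-6
        )


def test_transplant_anchor_side_unmoved():
    ext = build_peptide(8, -120.0, 120.0)
    helix = build_peptide(8, -57.0, -47.0)
    seg = extract_segment_dihedrals(helix, "A", (3, 6))
    out = transplant_segment_dihedrals(ext, "A", (3, 6), seg)
    # residues 1-2 (upstream anchor) bitwise unmoved
    upstream = [i for i, a in enumerate(ext.atoms) if a.res_id <= 2]
    np.testing.assert_array_equal(out.coords[upstream], ext.coords[upstream])


def test_transplant_downstream_anchor_mirror():
    ext = build_peptide(8, -120.0, 120.0)
    helix = build_peptide(8, -57.0, -47.0)
    seg = extract_segment_dihedrals(helix, "A", (3, 6))
    out = transplant_segment_dihedrals(ext, "A", (3, 6), seg, anchor="downstream")
    downstream = [i for i, a in enumerate(ext.atoms) if a.res_id >= 7]
    np.testing.assert_array_equal(out.coords[downstream], ext.coords[downstream])


def test_single_psi_rotation_matches_rotation_oracle():
    """Driving one psi rotates all downstream atoms rigidly about CA-C."""
    ext = build_peptide(6, -120.0, 120.0)
    seg = extract_segment_dihedrals(ext, "A", (1, 6))
    target_psi = -47.0
    rec = seg.for_residue(3)
    delta = target_psi - rec.psi
    rec.psi = target_psi
    for other in seg.residues:
        if other.res_id != 3:
            other.phi = other.psi = other.omega = None
    out = transplant_segment_dihedrals(ext, "A", (3, 3), seg, clamp_omega=False)
    # oracle: explicit right-handed rotation about the CA3->C3 axis
    ca = ext.atom("A", 3, "CA").coord
    c = ext.atom("A", 3, "C").coord
    R = rotation_about_axis(c - ca, delta)
    moved = [i for i, a in enumerate(ext.atoms) if a.res_id > 3]
    expected = (ext.coords[moved] - c) @ R.T + c
    np.testing.assert_allclose(out.coords[moved], expected, atol=1e-9)
    # upstream of the bond: unmoved
    upstream = [i for i, a in enumerate(ext.atoms) if a.res_id < 3]
    np.testing.assert_array_equal(out.coords[upstream], ext.coords[upstream])


def test_helical_angles_compact_an_extended_hexapeptide():
    ext = build_peptide(6, -120.0, 120.0)
    helix = build_peptide(6, -57.0, -47.0)
    seg = extract_segment_dihedrals(helix, "A", (1, 6))
    out = transplant_segment_dihedrals(ext, "A", (1, 6), seg)
    d_before = distance(ext.atom("A", 1, "CA").coord, ext.atom("A", 6, "CA").coord)
    d_after = distance(out.atom("A", 1, "CA").coord, out.atom("A", 6, "CA").coord)
    assert d_before > 15.0
    assert d_after < 10.0


def test_chain_break_detected():
    pep = build_peptide(6, -120.0, 120.0)
    broken = pep.copy()
    # push residues 4-6 away: C(3)-N(4) opens far beyond a bond
    for a in broken.atoms:
        if a.res_id >= 4:
            a.coord = a.coord + np.array([10.0, 0.0, 0.0])
    seg = extract_segment_dihedrals(pep, "A", (1, 6))
    with pytest.raises(ChainBreakError, match="3 and 4"):
        transplant_segment_dihedrals(broken, "A", (2, 5), seg)


def test_omega_clamped_to_trans_by_default():
    src = build_peptide(6, -100.0, 130.0, omega=172.0)
    tgt = build_peptide(6, -120.0, 120.0)
    seg = extract_segment_dihedrals(src, "A", (1, 6))
    out = transplant_segment_dihedrals(tgt, "A", (2, 5), seg)
    got = extract_segment_dihedrals(out, "A", (2, 5))
    for rec in got.residues:
        if rec.omega is not None:
            assert abs(rec.omega) == pytest.approx(180.0, abs=1e-4)
    # clamp off: the noisy template omega is reproduced
    out2 = transplant_segment_dihedrals(tgt, "A", (2, 5), seg, clamp_omega=False)
    got2 = extract_segment_dihedrals(out2, "A", (2, 5))
    mid = [r for r in got2.residues if r.omega is not None]
    assert any(abs(r.omega - 172.0) < 1e-4 for r in mid)


# ---------------------------------------------------------------------------
# grafting


def _tyr_like(res_id=689, res_name="TYR", chain="A", shift=(0.0, 0.0, 0.0)):
    shift = np.asarray(shift, float)
    coords = {
        "N": (0.0, 1.4, 0.0), "CA": (0.0, 0.0, 0.0), "C": (1.4, -0.5, 0.0),
        "O": (2.4, 0.1, 0.0),
        "CB": (-1.2, -0.8, 0.0), "CG": (-1.2, -2.3, 0.0),
        "CD1": (-0.1, -3.1, 0.3), "CD2": (-2.4, -2.9, -0.3),
        "CE1": (-0.1, -4.5, 0.3), "CE2": (-2.4, -4.3, -0.3),
        "CZ": (-1.3, -5.1, 0.0), "OH": (-1.3, -6.5, 0.0),
    }
    atoms = [
        Atom(serial=i + 1, name=n, element=("O" if n.startswith("O") else n[0]),
             res_name=res_name, res_id=res_id, chain=chain,
             coord=np.asarray(c, float) + shift)
        for i, (n, c) in enumerate(coords.items())
    ]
    return Structure(atoms=atoms)


def test_graft_identical_template_is_identity():
    target = _tyr_like()
    template = _tyr_like(shift=(5.0, 2.0, -3.0))
    out = graft_sidechain_template(
        target, 689, template, mapping=[("CA", "CA"), ("CB", "CB"), ("CG", "CG")]
    )
    assert len(out) == len(target)
    for a in target.atoms:
        np.testing.assert_allclose(
            out.atom("A", 689, a.name).coord, a.coord, atol=1e-9
        )


def test_graft_quinone_template_keeps_backbone_and_cb():
    target = _tyr_like()
    template = _tyr_like(res_name="TPQ", shift=(3.0, 1.0, 0.0))
    # decorate the template with a quinone-like extra oxygen
    template.atoms.append(
        Atom(serial=99, name="O2", element="O", res_name="TPQ", res_id=689,
             chain="A", coord=template.atom("A", 689, "CD1").coord + np.array([1.1, 0, 0]),
             hetero=True)
    )
    out = graft_sidechain_template(
        target, 689, template,
        mapping=[("CA", "CA"), ("CB", "CB"), ("CG", "CG")],
        rename="TPQ",
    )
    np.testing.assert_allclose(out.atom("A", 689, "CB").coord,
                               target.atom("A", 689, "CB").coord, atol=1e-9)
    np.testing.assert_array_equal(out.atom("A", 689, "N").coord,
                                  target.atom("A", 689, "N").coord)
    assert out.atom("A", 689, "O2").res_name == "TPQ"
    assert out.atom("A", 689, "CA").res_name == "TPQ"


def test_graft_missing_frame_atom_is_error():
    target = _tyr_like()
    target = Structure(atoms=[a for a in target.atoms if a.name != "CB"])
    template = _tyr_like()
    with pytest.raises(ValueError, match="CB"):
        graft_sidechain_template(
            target, 689, template, mapping=[("CA", "CA"), ("CB", "CB"), ("CG", "CG")]
        )
    with pytest.raises(ValueError, match="3 mapped"):
        graft_sidechain_template(target, 689, template, mapping=[("CA", "CA")])


# ---------------------------------------------------------------------------
# patches


def _tpq_lys_fixture():
    """Toy site variant before crosslinking: quinone carries an O2 on ring
    C2, the lysine arm is not yet bonded to the ring."""
    s = make_toy_active_site()
    i_c2 = s.index_of("A", 689, "C2")
    i_nz = s.index_of("A", 653, "NZ")
    s.bonds.discard(tuple(sorted((i_c2, i_nz))))
    c2 = s.atoms[i_c2].coord
    ring_center = np.mean(
        [s.atom("A", 689, n).coord for n in ("C1", "C2", "C3", "C4", "C5", "C6")], axis=0
    )
    out_dir = (c2 - ring_center) / np.linalg.norm(c2 - ring_center)
    # rotate O2 out of the lysine direction so the frame stays well-formed
    o2 = c2 + 1.25 * (rotation_about_axis(np.array([0.0, 1.0, 0.0]), 40.0) @ out_dir)
    s.atoms.append(
        Atom(serial=max(a.serial for a in s.atoms) + 1, name="O2", element="O",
             res_name="TPQ", res_id=689, chain="A", coord=o2, hetero=True)
    )
    s.add_bond(len(s.atoms) - 1, i_c2)
    for a in s.atoms:
        if a.res_id == 689:
            a.res_name = "TPQ"
    return s


def _graph_key(s: Structure):
    return {
        frozenset(((s.atoms[i].res_id, s.atoms[i].name), (s.atoms[j].res_id, s.atoms[j].name)))
        for i, j in s.bonds
    }


def test_crosslink_patch_bookkeeping():
    s = _tpq_lys_fixture()
    patch = make_ltq2hp_crosslink_patch()
    out = apply_patch(s, patch)
    assert len(out) == len(s) - 1                      # one oxygen removed
    assert len(out.bonds) == len(s.bonds)              # one bond out, one in
    i_nz = out.index_of("A", 653, "NZ")
    i_c2 = out.index_of("A", 689, "C2")
    assert tuple(sorted((i_nz, i_c2))) in out.bonds    # the new crosslink
    assert not any(a.name == "O2" for a in out.atoms)
    assert out.atom("A", 689, "C2").res_name == "LTQ"
    # exactly one inter-residue bond between 653 and 689
    inter = [
        b for b in out.bonds
        if {out.atoms[b[0]].res_id, out.atoms[b[1]].res_id} == {653, 689}
    ]
    assert len(inter) == 1


def test_patch_inversion_restores_graph():
    s = _tpq_lys_fixture()
    patch = make_ltq2hp_crosslink_patch()
    out = apply_patch(s, patch)
    restored = apply_patch(out, invert_patch(patch, s))
    assert len(restored) == len(s)
    assert _graph_key(restored) == _graph_key(s)
    o2 = next(a for a in restored.atoms if a.name == "O2")
    o2_orig = next(a for a in s.atoms if a.name == "O2")
    np.testing.assert_allclose(o2.coord, o2_orig.coord, atol=1e-9)
    assert o2.res_name == "TPQ"


def test_hydrazone_removal_patch():
    s = _tpq_lys_fixture()
    s = apply_patch(s, make_ltq2hp_crosslink_patch())
    # decorate with a minimal 2HP-like arm on C5: two nitrogens
    i_c5 = s.index_of("A", 689, "C5")
    c5 = s.atoms[i_c5].coord
    c4 = s.atom("A", 689, "C4").coord
    ring_center = np.mean(
        [s.atom("A", 689, n).coord for n in ("C1", "C2", "C3", "C4", "C5", "C6")], axis=0
    )
    n1 = c5 + 1.35 * (c5 - ring_center) / np.linalg.norm(c5 - ring_center)
    n3 = n1 + np.array([0.0, 1.2, 0.6])
    for nm, pos in (("N1", n1), ("N3", n3)):
        s.atoms.append(
            Atom(serial=max(a.serial for a in s.atoms) + 1, name=nm, element="N",
                 res_name="LTQ", res_id=689, chain="A", coord=pos, hetero=True)
        )
    s.add_bond(i_c5, s.index_of("A", 689, "N1"))
    s.add_bond(s.index_of("A", 689, "N1"), s.index_of("A", 689, "N3"))
    patch = make_ltq2hp_to_ltq_patch(hydrazone_atoms=("N1", "N3"))
    out = apply_patch(s, patch)
    assert not any(a.name in ("N1", "N3") for a in out.atoms)
    o5 = out.atom("A", 689, "O5")
    assert distance(o5.coord, out.atom("A", 689, "C5").coord) == pytest.approx(1.23, abs=1e-9)
    assert len(out) == len(s) - 2 + 1


def test_dangling_bond_is_error():
    s = _tpq_lys_fixture()
    from ltqkit.remodel import CofactorPatch

    bad = CofactorPatch(name="bad", atoms_deleted=[(689, "O2")])  # bond not deleted
    with pytest.raises(PatchError, match="dangle"):
        apply_patch(s, bad)


def test_patch_missing_atom_is_error():
    s = make_toy_active_site()
    patch = make_ltq2hp_crosslink_patch()  # no O2 in the mature toy site
    with pytest.raises(PatchError, match="O2"):
        apply_patch(s, patch)


def test_patch_file_round_trip(tmp_path):
    text = """
# crosslink patch
unbond 689:O2 689:C2
delete 689 O2
bond 653:NZ 689:C2
rename 689 LTQ
"""
    patch = parse_patch_file(text)
    s = _tpq_lys_fixture()
    out = apply_patch(s, patch)
    assert len(out) == len(s) - 1
    assert out.atom("A", 689, "C2").res_name == "LTQ"
    with pytest.raises(PatchError, match="line"):
        parse_patch_file("frobnicate 1 2 3")


def test_patch_file_add_placement():
    text = "add 689 O5 O 689:C3 689:C4 689:C5 1.23 120.0 180.0\nbond 689:O5 689:C5\n"
    patch = parse_patch_file(text)
    s = make_toy_active_site()
    out = apply_patch(s, patch)
    o5 = out.atom("A", 689, "O5")
    assert distance(o5.coord, out.atom("A", 689, "C5").coord) == pytest.approx(1.23, abs=1e-9)
    assert angle(
        out.atom("A", 689, "C4").coord, out.atom("A", 689, "C5").coord, o5.coord
    ) == pytest.approx(120.0, abs=1e-9)


# ---------------------------------------------------------------------------
# metal swap


def test_swap_metal(toy_site):
    zn_site = swap_metal(toy_site, "CU", "ZN")
    a = zn_site.atoms[0]
    assert a.element == "ZN" and a.name == "ZN" and a.res_name == "ZN"
    np.testing.assert_array_equal(a.coord, toy_site.atoms[0].coord)
    # and back, as the maturation step does
    cu_site = swap_metal(zn_site, "ZN", "CU")
    assert cu_site.atoms[0].element == "CU"


def test_swap_metal_errors(toy_site):
    with pytest.raises(ValueError, match="no ZN"):
        swap_metal(toy_site, "ZN", "CU")
    doubled = toy_site.copy()
    doubled.atoms.append(toy_site.atoms[0].copy())
    with pytest.raises(ValueError, match="2 CU"):
        swap_metal(doubled, "CU", "ZN")


# ---------------------------------------------------------------------------
# coordination waters


def _three_donor_site():
    site = make_ideal_metal_site("square-pyramidal")
    # keep the metal and three basal donors at (1,0,0), (-1,0,0), (0,1,0)
    return Structure(atoms=[site.atoms[i].copy() for i in (0, 2, 3, 4)])


def test_weq_fills_basal_gap():
    s = place_coordination_waters(_three_donor_site(), 0, [1, 2, 3])
    weq = next(a for a in s.atoms if a.res_id == 901)
    gap_angle = angle(weq.coord, s.atoms[0].coord, np.array([0.0, 2.1, 0.0]))
    assert gap_angle == pytest.approx(180.0, abs=5.0)  # trans to the remaining donor
    assert distance(weq.coord, s.atoms[0].coord) == pytest.approx(2.00, abs=1e-9)


def test_wax_normal_to_basal_plane():
    s = place_coordination_waters(_three_donor_site(), 0, [1, 2, 3])
    wax = next(a for a in s.atoms if a.res_id == 902)
    weq = next(a for a in s.atoms if a.res_id == 901)
    assert distance(wax.coord, s.atoms[0].coord) == pytest.approx(2.40, abs=1e-9)
    assert angle(wax.coord, s.atoms[0].coord, weq.coord) == pytest.approx(90.0, abs=5.0)


def test_waters_complete_square_pyramid():
    s = place_coordination_waters(_three_donor_site(), 0, [1, 2, 3])
    sphere = find_coordination_sphere(s, s.atoms[0])
    assert sphere.coordination_number == 5
    res = addison_tau(sphere)
    assert res.tau < 0.1
    assert res.label == "square-pyramidal"


def test_water_hydrogens_at_120_degrees():
    s = place_coordination_waters(_three_donor_site(), 0, [1, 2, 3], add_hydrogens=True)
    m = s.atoms[0].coord
    for rid in (901, 902):
        o = s.atom("A", rid, "O").coord
        for hn in ("H1", "H2"):
            h = s.atom("A", rid, hn).coord
            assert angle(m, o, h) == pytest.approx(120.0, abs=1e-6)


def test_balanced_donors_have_no_gap():
    site = make_ideal_metal_site("square-pyramidal")
    s = Structure(atoms=[site.atoms[i].copy() for i in (0, 2, 3, 4, 5)])
    with pytest.raises(ValueError, match="gap"):
        place_coordination_waters(s, 0, [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# restraints


def test_restraints_zero_on_conforming_fixture():
    s = place_coordination_waters(_three_donor_site(), 0, [1, 2, 3], add_hydrogens=True)
    specs = [
        RestraintSpec(kind="improper-planarity",
                      atoms=((11, "N"), (1, "CU"), (13, "N"), (12, "N")),
                      label="basal plane"),
        RestraintSpec(kind="angle", atoms=((1, "CU"), (901, "O"), (901, "H1")),
                      target=120.0, label="Weq H1"),
        RestraintSpec(kind="angle", atoms=((1, "CU"), (902, "O"), (902, "H2")),
                      target=120.0, label="Wax H2"),
    ]
    for r in evaluate_restraints(s, specs):
        assert r.deviation == pytest.approx(0.0, abs=1e-6)
        assert r.penalty == pytest.approx(0.0, abs=1e-10)


def test_angle_restraint_deviation_arithmetic():
    atoms = [
        Atom(serial=1, name="CU", element="CU", res_name="CU", res_id=1,
             chain="A", coord=(0, 0, 0), hetero=True),
        Atom(serial=2, name="O", element="O", res_name="HOH", res_id=2,
             chain="A", coord=(2.0, 0, 0), hetero=True),
        Atom(serial=3, name="H1", element="H", res_name="HOH", res_id=2,
             chain="A", coord=(2.0 + np.cos(np.radians(180 - 109.5)),
                               np.sin(np.radians(180 - 109.5)), 0.0), hetero=True),
    ]
    s = Structure(atoms=atoms)
    [r] = evaluate_restraints(
        s, [RestraintSpec(kind="angle", atoms=((1, "CU"), (2, "O"), (2, "H1")),
                          target=120.0, weight=2.0)]
    )
    assert r.value == pytest.approx(109.5, abs=1e-6)
    assert r.deviation == pytest.approx(10.5, abs=1e-6)
    assert r.penalty == pytest.approx(2.0 * 10.5**2, rel=1e-6)


def test_planarity_deviation_nonzero_for_pyramidalised_site():
    atoms = [
        Atom(serial=1, name="N1", element="N", res_name="LIG", res_id=1,
             chain="A", coord=(2.0, 0, 0)),
        Atom(serial=2, name="CU", element="CU", res_name="CU", res_id=2,
             chain="A", coord=(0, 0, 0.5), hetero=True),  # lifted out of plane
        Atom(serial=3, name="N2", element="N", res_name="LIG", res_id=3,
             chain="A", coord=(0, 2.0, 0)),
        Atom(serial=4, name="N3", element="N", res_name="LIG", res_id=4,
             chain="A", coord=(-2.0, 0, 0)),
    ]
    s = Structure(atoms=atoms)
    [r] = evaluate_restraints(
        s, [RestraintSpec(kind="improper-planarity",
                          atoms=((1, "N1"), (2, "CU"), (3, "N2"), (4, "N3")))]
    )
    assert r.deviation > 5.0
    assert r.penalty == pytest.approx(r.deviation**2, rel=1e-9)
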