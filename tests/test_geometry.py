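"""Dihedrals, valence angles, strain contacts and Kabsch superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ramastrain import (
    backbone_dihedrals, build_peptide, cb_contact_distances, delta_omega,
    dihedral, kabsch_rmsd, surrounding_contacts, valence_angles,
)
from ramastrain.errors import GeometryError
from ramastrain.geometry import MONITORED_ANGLES, bond_angle, wrap_angle
from ramastrain.structures import AtomRecord, ResidueRecord


def rigid_transform(coords, rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-50, 50, 3)
    return coords @ R.as_matrix().T + t


# ---------------------------------------------------------------------------
# elementary torsion

@pytest.mark.parametrize("p4,expected", [
    ((1, 1, 0), 0.0),      # eclipsed cis
    ((-1, 1, 0), 180.0),   # anti trans
    ((0, 1, 1), -90.0),    # right-handed quarter turn
])
def test_dihedral_reference_values(p4, expected):
    val = dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
    assert val == pytest.approx(expected, abs=1e-9)


def test_dihedral_matches_projection_oracle(rng):
    """Cross-check against an independent half-plane projection oracle:
    project the outer bonds onto the plane normal to the central bond and
    take the signed angle between the projections."""
    for _ in range(50):
        pts = rng.uniform(-5, 5, (4, 3))
        b2 = pts[2] - pts[1]
        b2u = b2 / np.linalg.norm(b2)
        a = (pts[0] - pts[1])
        a = a - (a @ b2u) * b2u
        d = (pts[3] - pts[2])
        d = d - (d @ b2u) * b2u
        if min(np.linalg.norm(a), np.linalg.norm(d)) < 1e-6:
            continue
        oracle = math.degrees(math.atan2(float(np.cross(a, d) @ b2u),
                                         float(a @ d)))
        assert dihedral(*pts) == pytest.approx(wrap_angle(oracle), abs=1e-9)


def test_dihedral_invariant_under_chain_reversal(rng):
    """The Klyne–Prelog torsion is independent of the traversal direction:
    the angle of D–C–B–A equals that of A–B–C–D, sign included."""
    for _ in range(25):
        pts = rng.uniform(-5, 5, (4, 3))
        try:
            fwd = dihedral(*pts)
        except GeometryError:
            continue
        assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)


def test_dihedral_rigid_invariance(rng):
    pts = rng.uniform(-5, 5, (4, 3))
    ref = dihedral(*pts)
    for _ in range(10):
        moved = rigid_transform(pts, rng)
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)


def test_degenerate_geometry_raises():
    with pytest.raises(GeometryError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))  # collinear
    with pytest.raises(GeometryError):
        dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))  # coincident


# ---------------------------------------------------------------------------
# backbone dihedrals

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.floats(-179.0, 180.0), st.floats(-179.0, 180.0)),
    min_size=3, max_size=8))
def test_build_measure_round_trip_is_identity(phi_psi):
    """Building a peptide at arbitrary (φ,ψ) and re-measuring returns the
    request to 1e-6° — the end-to-end oracle of the geometry pipeline."""
    n = len(phi_psi)
    plan = [(None, phi_psi[0][1])] + list(phi_psi[1:-1]) + \
        [(phi_psi[-1][0], None)]
    model = build_peptide("A" * n, plan)
    recs = backbone_dihedrals(model)
    assert recs[0].phi is None and recs[0].omega is None
    assert recs[-1].psi is None
    for i in range(1, n - 1):
        assert recs[i].phi == pytest.approx(phi_psi[i][0], abs=1e-6)
        assert recs[i].psi == pytest.approx(phi_psi[i][1], abs=1e-6)
        assert abs(recs[i].omega) == pytest.approx(180.0, abs=1e-6)


def test_omega_round_trip():
    model = build_peptide("AAAA", [(None, -47.0), (-57.0, -47.0),
                                   (-57.0, -47.0), (-57.0, None)],
                          omega=[180.0, 175.0, -170.0, 5.0])
    recs = backbone_dihedrals(model)
    assert recs[1].omega == pytest.approx(175.0, abs=1e-6)
    assert recs[2].omega == pytest.approx(-170.0, abs=1e-6)
    assert recs[3].omega == pytest.approx(5.0, abs=1e-6)


def test_chain_break_gives_undefined_dihedrals(helix15):
    """Pulling the second half of the chain away breaks φ/ψ/ω chaining."""
    import copy
    model = copy.deepcopy(helix15)
    chain = model.chains["A"]
    for res in chain[7:]:
        for atom in res.atoms:
            atom.coords = atom.coords + np.array([50.0, 0.0, 0.0])
    recs = backbone_dihedrals(model)
    assert recs[6].psi is None     # break after residue 7 (index 6)
    assert recs[7].phi is None and recs[7].omega is None
    assert recs[5].psi is not None


# ---------------------------------------------------------------------------
# peptide planarity

@pytest.mark.parametrize("omega,expected", [
    (175.0, -5.0), (-178.0, 2.0), (6.0, 6.0), (180.0, 0.0), (-90.0, -90.0),
    (91.0, -89.0),
])
def test_delta_omega(omega, expected):
    assert delta_omega(omega) == pytest.approx(expected, abs=1e-9)


def test_delta_omega_none_passthrough():
    assert delta_omega(None) is None


# ---------------------------------------------------------------------------
# valence angles

def test_valence_angles_reproduce_reference_table(geometry):
    model = build_peptide("AAA", [(None, -47.0), (-65.0, 120.0), (-57.0, None)])
    res = model.polymer_residues()[1]
    angles = valence_angles(model, res).angles
    for name in MONITORED_ANGLES:
        assert angles[name] == pytest.approx(
            geometry.mean("ALA", name), abs=1e-6), name


def test_valence_angle_override_is_honoured(geometry):
    model = build_peptide("AAA", [(None, -47.0), (-65.0, 120.0), (-57.0, None)],
                          angle_overrides={(1, "NCaCb"): 116.4})
    res = model.polymer_residues()[1]
    assert valence_angles(model, res).angles["NCaCb"] == pytest.approx(
        116.4, abs=1e-6)


def test_gly_has_no_cb_angles():
    model = build_peptide("AGA", [(None, -47.0), (90.0, -170.0), (-57.0, None)])
    res = model.polymer_residues()[1]
    angles = valence_angles(model, res).angles
    assert angles["NCaCb"] is None and angles["CbCaC"] is None
    assert angles["NCaC"] is not None


# ---------------------------------------------------------------------------
# strain contacts

def test_cb_contacts_match_direct_coordinate_oracle(eps_tripeptide):
    res = eps_tripeptide.polymer_residues()[1]
    d_prev, d_next = cb_contact_distances(eps_tripeptide, res)
    cb = res.coord("CB")
    o_prev = eps_tripeptide.polymer_residues()[0].coord("O")
    n_next = eps_tripeptide.polymer_residues()[2].coord("N")
    assert d_prev == pytest.approx(float(np.linalg.norm(cb - o_prev)), abs=1e-12)
    assert d_next == pytest.approx(float(np.linalg.norm(cb - n_next)), abs=1e-12)


def test_cb_contacts_strained_in_epsilon_conformation(eps_tripeptide):
    """The ε conformation forces both Cβ contacts below the 3.1 Å strain
    threshold — the steric reason the region is forbidden to non-Gly."""
    res = eps_tripeptide.polymer_residues()[1]
    d_prev, d_next = cb_contact_distances(eps_tripeptide, res)
    assert d_prev < 3.1 and d_next < 3.1


def test_cb_contacts_undefined_for_gly():
    model = build_peptide("AGA", [(None, -47.0), (117.0, -170.0), (-57.0, None)])
    res = model.polymer_residues()[1]
    assert cb_contact_distances(model, res) == (None, None)


def test_surrounding_contacts_planted_atom(helix15):
    import copy
    model = copy.deepcopy(helix15)
    res = model.polymer_residues()[7]
    cb = res.coord("CB")
    probe = cb + np.array([3.0, 0.0, 0.0])
    extra = ResidueRecord("B", 1, "", "HOH",
                          [AtomRecord("O", "O", probe)], het=True)
    model.chains["B"] = [extra]
    hits = surrounding_contacts(model, res, "CB", 3.05)
    assert len(hits) == 1
    assert hits[0].distance == pytest.approx(3.0, abs=1e-9)
    assert hits[0].atom_b[1] == "O"


def test_surrounding_contacts_isolated_residue():
    model = build_peptide("A", [(None, None)])
    res = model.polymer_residues()[0]
    assert surrounding_contacts(model, res, "CB", 5.0) == []


# ---------------------------------------------------------------------------
# Kabsch superposition

def test_kabsch_identity_and_rigid_invariance(rng):
    A = rng.uniform(-10, 10, (20, 3))
    assert kabsch_rmsd(A, A)[0] == pytest.approx(0.0, abs=1e-12)
    moved = rigid_transform(A, rng)
    assert kabsch_rmsd(moved, A)[0] == pytest.approx(0.0, abs=1e-9)


def test_kabsch_matches_scipy_oracle(rng):
    """Dual-route check against scipy's independent superposition."""
    for _ in range(10):
        A = rng.uniform(-10, 10, (15, 3))
        B = A + rng.normal(0, 1.0, A.shape)
        ours = kabsch_rmsd(A, B)[0]
        _, rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert ours == pytest.approx(rssd / math.sqrt(len(A)), abs=1e-9)


def test_kabsch_symmetric(rng):
    A = rng.uniform(-10, 10, (12, 3))
    B = A + rng.normal(0, 0.5, A.shape)
    assert kabsch_rmsd(A, B)[0] == pytest.approx(kabsch_rmsd(B, A)[0], abs=1e-9)


def test_kabsch_mirror_image_keeps_positive_rmsd(rng):
    A = rng.uniform(-10, 10, (12, 3))
    mirror = A * np.array([-1.0, 1.0, 1.0])
    rmsd, R, _ = kabsch_rmsd(mirror, A)
    assert rmsd > 0.1
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_shape_mismatch_raises(rng):
    with pytest.raises(ValueError):
        kabsch_rmsd(rng.uniform(size=(5, 3)), rng.uniform(size=(6, 3)))


def test_bond_angle_right_angle():
    assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
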