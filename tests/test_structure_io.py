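"""Structure and trajectory I/O: round trips, altlocs, resolution metadata."""

import numpy as np
import pytest

from ramastrain import (
    build_peptide, read_structure, read_trajectory, synth_trajectory,
    write_structure, write_trajectory,
)
from ramastrain.errors import EmptyModelError, FormatError, StructureError
from ramastrain.structures import StructureModel

from conftest import make_helix

MINIMAL_CIF = """data_test
_refine.ls_d_res_high {res_tag}
_exptl.method 'X-RAY DIFFRACTION'
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 0.0 0.0 0.0 1.00 10.0 A 1
ATOM 2 C CA . ALA A 1 1 1.458 0.0 0.0 1.00 10.0 A 1
ATOM 3 C C . ALA A 1 1 2.0 1.4 0.0 1.00 10.0 A 1
"""


def test_pdb_round_trip_preserves_model(tmp_path, helix15):
    helix15.resolution = 1.8
    path = tmp_path / "helix.pdb"
    write_structure(helix15, path)
    back = read_structure(path, format="pdb")[0]
    assert back.resolution == pytest.approx(1.8, abs=1e-6)
    res_a = helix15.polymer_residues()
    res_b = back.polymer_residues()
    assert [(r.seq_number, r.res_name) for r in res_a] == \
        [(r.seq_number, r.res_name) for r in res_b]
    assert np.abs(back.all_coords() - helix15.all_coords()).max() < 1e-3


def test_altloc_highest_occupancy_wins(tmp_path):
    pdb = (
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.70 10.00           N\n"
        "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.30 10.00           N\n"
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C\n"
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C\n"
        "END\n")
    path = tmp_path / "alt.pdb"
    path.write_text(pdb)
    model = read_structure(path)[0]
    atom = next(model.residues()).atom("N")
    assert atom.altloc == "A"
    assert np.allclose(atom.coords, [0.0, 0.0, 0.0])


def test_altloc_tie_broken_by_smallest_label(tmp_path):
    pdb = (
        "ATOM      1  N  BALA A   1       9.000   0.000   0.000  0.50 10.00           N\n"
        "ATOM      2  N  AALA A   1       0.000   0.000   0.000  0.50 10.00           N\n"
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C\n"
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C\n"
        "END\n")
    path = tmp_path / "tie.pdb"
    path.write_text(pdb)
    model = read_structure(path)[0]
    assert next(model.residues()).atom("N").altloc == "A"


def test_mmcif_resolution_from_refinement_limit(tmp_path):
    path = tmp_path / "m.cif"
    path.write_text(MINIMAL_CIF.format(res_tag="1.64"))
    model = read_structure(path, format="mmcif")[0]
    assert model.resolution == pytest.approx(1.64)
    assert "X-RAY" in model.experiment_type


def test_mmcif_missing_resolution_is_none(tmp_path):
    path = tmp_path / "m.cif"
    path.write_text(MINIMAL_CIF.format(res_tag="?"))
    model = read_structure(path, format="mmcif")[0]
    assert model.resolution is None


def test_write_empty_model_raises(tmp_path):
    empty = StructureModel(structure_id="empty")
    with pytest.raises(EmptyModelError):
        write_structure(empty, tmp_path / "x.pdb")


def test_unparseable_file_raises_format_error(tmp_path):
    path = tmp_path / "junk.cif"
    path.write_text("this is not a structure\n")
    with pytest.raises((FormatError, EmptyModelError)):
        read_structure(path, format="mmcif")


def test_long_chain_written_line_per_atom(tmp_path):
    n = 1000
    model = make_helix(n)
    path = tmp_path / "long.pdb"
    write_structure(model, path)
    atom_lines = [ln for ln in path.read_text().splitlines()
                  if ln.startswith("ATOM")]
    assert len(atom_lines) == model.atom_count()
    back = read_structure(path)[0]
    assert back.atom_count() == model.atom_count()


def test_single_model_trajectory_equals_structure(tmp_path, helix15):
    path = tmp_path / "one.pdb"
    write_structure(helix15, path)
    traj = read_trajectory(path)
    assert traj.n_frames == 1
    assert np.abs(traj.coords[0] - helix15.all_coords()).max() < 1e-3


def test_multi_frame_round_trip(tmp_path, helix15):
    traj = synth_trajectory(20, helix15, fluctuation_profile=[0.2] * 15, seed=5)
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.n_frames == 20
    assert back.n_atoms == traj.n_atoms
    assert np.abs(back.coords - traj.coords).max() < 1e-3


def test_inconsistent_frame_atom_count_raises(tmp_path, helix15):
    traj = synth_trajectory(2, helix15, seed=1)
    path = tmp_path / "bad.pdb"
    write_trajectory(traj, path)
    lines = path.read_text().splitlines()
    # drop one atom from the second model
    out, dropped, in_second = [], False, False
    for ln in lines:
        if ln.startswith("MODEL") and "2" in ln.split():
            in_second = True
        if in_second and not dropped and ln.startswith("ATOM"):
            dropped = True
            continue
        out.append(ln)
    path.write_text("\n".join(out) + "\n")
    with pytest.raises(StructureError):
        read_trajectory(path)


def test_altloc_resolution_deterministic(tmp_path):
    pdb = (
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.70 10.00           N\n"
        "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.30 10.00           N\n"
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C\n"
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C\n"
        "END\n")
    path = tmp_path / "alt.pdb"
    path.write_text(pdb)
    first = read_structure(path)[0].all_coords()
    for _ in range(3):
        assert np.array_equal(read_structure(path)[0].all_coords(), first)
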