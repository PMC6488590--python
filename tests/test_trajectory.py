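"""Trajectory statistics: occupancy, RMSD/Rg, pseudo-B factors, RMSIP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ramastrain import (
    Trajectory, build_peptide, dihedral_series, forbidden_quadrant,
    pseudo_bfactors_from_traj, region_occupancy, rg_series, rmsd_series,
    rmsip, standardized_bfactors, synth_trajectory,
)
from ramastrain.errors import DegenerateProfileError
from ramastrain.structures import AtomRecord, ResidueRecord, StructureModel
from ramastrain.synthetic import (
    helix_sampler, orthogonal_mode_trajectory, quadrant_sampler,
)
from ramastrain.trajectory import EIGHT_PI2

from conftest import make_helix


def make_nonapeptide():
    return make_helix(9)


def point_cloud_model(points):
    """One chain of single-CA residues at the given coordinates."""
    residues = [ResidueRecord("A", i + 1, "", "ALA",
                              [AtomRecord("CA", "C", p)])
                for i, p in enumerate(points)]
    return StructureModel("cloud", 1, {"A": residues})


# ---------------------------------------------------------------------------
# dihedral series and occupancy

def test_single_frame_series_returns_planted_dihedrals():
    model = build_peptide("AAA", [(None, -47.0), (117.3, -170.9),
                                  (-57.0, None)])
    traj = Trajectory(model, model.all_coords()[None, :, :])
    series = dihedral_series(traj, 2)
    assert len(series) == 1
    assert series[0][0] == pytest.approx(117.3, abs=1e-6)
    assert series[0][1] == pytest.approx(-170.9, abs=1e-6)


def test_terminal_residue_series_raises():
    model = make_nonapeptide()
    traj = Trajectory(model, model.all_coords()[None, :, :])
    with pytest.raises(ValueError):
        dihedral_series(traj, 1)


def test_full_epsilon_plan_always_in_quadrant():
    template = make_nonapeptide()
    traj = synth_trajectory(50, template, target_residue=5,
                            occupancy_plan=[(quadrant_sampler(), 1.0)],
                            seed=4)
    series = dihedral_series(traj, 5)
    assert len(series) == traj.n_frames
    occ = region_occupancy(series, forbidden_quadrant, residue=5)
    assert occ.fraction_in_region == 1.0


def test_planted_occupancy_recovered_within_binomial_error():
    template = make_nonapeptide()
    n, p = 2000, 0.3
    traj = synth_trajectory(n, template, target_residue=5,
                            occupancy_plan=[(quadrant_sampler(), p),
                                            (helix_sampler(), 1 - p)],
                            seed=99)
    series = dihedral_series(traj, 5)
    occ = region_occupancy(series, forbidden_quadrant, residue=5)
    tol = 3.0 * np.sqrt(p * (1 - p) / n)
    assert abs(occ.fraction_in_region - p) < tol


def test_occupancy_window_mixture_identity():
    """Occupancy over a window equals the frame-weighted mixture of the
    occupancies over any partition of that window."""
    series = [(100.0, -170.0)] * 30 + [(-57.0, -47.0)] * 70
    whole = region_occupancy(series, forbidden_quadrant, (0, 100))
    first = region_occupancy(series, forbidden_quadrant, (0, 40))
    second = region_occupancy(series, forbidden_quadrant, (40, 100))
    mixture = (40 * first.fraction_in_region
               + 60 * second.fraction_in_region) / 100
    assert whole.fraction_in_region == pytest.approx(mixture, abs=1e-12)
    prefix = region_occupancy(series, forbidden_quadrant, (30, 100))
    assert prefix.fraction_in_region == 0.0


def test_empty_window_raises():
    with pytest.raises(ValueError):
        region_occupancy([(0.0, 0.0)], forbidden_quadrant, (1, 1))


# ---------------------------------------------------------------------------
# RMSD and Rg

def test_rmsd_zero_against_own_reference():
    model = make_nonapeptide()
    traj = Trajectory(model, np.repeat(model.all_coords()[None], 3, axis=0))
    assert np.allclose(rmsd_series(traj), 0.0, atol=1e-12)


def test_rmsd_detects_displaced_frame(rng):
    model = make_nonapeptide()
    coords = np.repeat(model.all_coords()[None], 2, axis=0)
    coords[1] += rng.normal(0, 0.5, coords[1].shape)
    traj = Trajectory(model, coords)
    series = rmsd_series(traj)
    assert series[0] == pytest.approx(0.0, abs=1e-12)
    assert series[1] > 0.1


def test_rg_single_atom_is_zero():
    model = point_cloud_model([np.zeros(3)])
    traj = Trajectory(model, model.all_coords()[None])
    assert rg_series(traj)[0] == pytest.approx(0.0, abs=1e-12)


def test_rg_two_unit_masses_two_angstrom_apart():
    model = point_cloud_model([np.zeros(3), np.array([2.0, 0.0, 0.0])])
    traj = Trajectory(model, model.all_coords()[None])
    assert rg_series(traj)[0] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# B-factors

def test_standardized_bfactors_direct_arithmetic():
    prof = standardized_bfactors([10.0, 20.0, 30.0])
    assert prof.standardized == pytest.approx([-1.2247, 0.0, 1.2247],
                                              abs=1e-4)
    assert prof.standardized.mean() == pytest.approx(0.0, abs=1e-12)
    assert prof.standardized.std() == pytest.approx(1.0, abs=1e-12)


def test_standardized_bfactors_affine_invariant(rng):
    values = rng.uniform(5, 50, 40)
    base = standardized_bfactors(values).standardized
    scaled = standardized_bfactors(3.7 * values + 11.0).standardized
    assert np.allclose(base, scaled, atol=1e-10)
    r = np.corrcoef(base, scaled)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_constant_profile_raises():
    with pytest.raises(DegenerateProfileError):
        standardized_bfactors([7.0, 7.0, 7.0])


def test_rigid_body_motion_gives_zero_pseudo_b(rng):
    model = make_nonapeptide()
    base = model.all_coords()
    frames = []
    for _ in range(20):
        R = Rotation.random(
            random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.uniform(-20, 20, 3)
        frames.append(base @ R.T + t)
    traj = Trajectory(model, np.array(frames))
    assert np.max(pseudo_bfactors_from_traj(traj)) < 1e-12


def test_high_fluctuation_residue_has_max_pseudo_b():
    model = make_helix(11)
    sigma = np.full(11, 0.1)
    sigma[5] = 0.3
    traj = synth_trajectory(400, model, fluctuation_profile=sigma, seed=21)
    pseudo = pseudo_bfactors_from_traj(traj)
    assert int(np.argmax(pseudo)) == 5


def test_isotropic_fluctuation_matches_analytic_msf():
    """Isotropic Gaussian displacement of variance σ² per coordinate gives
    MSF = 3σ², hence pseudo-B = 8π²σ²."""
    model = make_helix(60)
    sigma = 0.2
    traj = synth_trajectory(2000, model,
                            fluctuation_profile=np.full(60, sigma), seed=8)
    pseudo = pseudo_bfactors_from_traj(traj)
    expected = EIGHT_PI2 * sigma ** 2
    assert np.mean(pseudo) == pytest.approx(expected, rel=0.10)


# ---------------------------------------------------------------------------
# RMSIP

def test_rmsip_identical_windows_is_one():
    traj, n_modes, n_frames = orthogonal_mode_trajectory()
    with pytest.warns(UserWarning, match="overlap"):
        overlap = rmsip(traj, (0, n_frames), (0, n_frames), n_modes=n_modes)
    assert overlap.rmsip == pytest.approx(1.0, abs=1e-9)


def test_rmsip_orthogonal_subspaces_is_zero():
    traj, n_modes, n_frames = orthogonal_mode_trajectory()
    overlap = rmsip(traj, (0, n_frames), (n_frames, 2 * n_frames),
                    n_modes=n_modes)
    assert overlap.rmsip == pytest.approx(0.0, abs=1e-6)


def test_rmsip_complete_bases_give_one(rng):
    """With n_modes equal to the full 3N dimensionality both windows span
    everything, so the RMSIP of complete bases is 1."""
    model = point_cloud_model(list(rng.uniform(-5, 5, (4, 3))))
    base = model.all_coords()
    coords = base[None] + rng.normal(0, 0.1, (30, 4, 3))
    traj = Trajectory(model, coords)
    overlap = rmsip(traj, (0, 15), (15, 30), n_modes=12)
    assert overlap.rmsip == pytest.approx(1.0, abs=1e-9)


def test_rmsip_bounded_for_random_trajectories(rng):
    model = make_nonapeptide()
    for trial in range(3):
        coords = model.all_coords()[None] + \
            rng.normal(0, 0.3, (24, model.atom_count(), 3))
        traj = Trajectory(model, coords)
        overlap = rmsip(traj, (0, 12), (12, 24), n_modes=5)
        assert 0.0 <= overlap.rmsip <= 1.0


def test_rmsip_overlapping_windows_warn():
    traj, n_modes, n_frames = orthogonal_mode_trajectory()
    with pytest.warns(UserWarning):
        rmsip(traj, (0, n_frames), (n_frames // 2, n_frames), n_modes=4)


def test_rmsip_too_few_frames_raises():
    traj, _, n_frames = orthogonal_mode_trajectory()
    with pytest.raises(ValueError):
        rmsip(traj, (0, 3), (3, 6), n_modes=10)
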