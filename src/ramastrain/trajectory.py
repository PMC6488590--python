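"""MD-trajectory post-processing.

Per-residue dihedral time series and region occupancy over an equilibration
window, RMSD and radius-of-gyration series, RMSF-derived pseudo B-factors
with Carugo-style standardization (per-structure z-scores), and the root
mean square inner product (RMSIP) between the essential-dynamics subspaces
of two trajectory windows — the convergence check computed between the two
halves of an equilibrated trajectory over the first 10 covariance
eigenvectors of the Cα motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ramastrain.errors import DegenerateProfileError
from ramastrain.geometry import backbone_dihedrals, kabsch_rmsd
from ramastrain.structures import Trajectory

__all__ = [
    "OccupancySummary", "BFactorProfile", "SubspaceOverlap",
    "dihedral_series", "region_occupancy", "rmsd_series", "rg_series",
    "standardized_bfactors", "pseudo_bfactors_from_traj", "rmsip",
]

EIGHT_PI2 = 8.0 * np.pi ** 2


@dataclass
class OccupancySummary:
    """Fraction of window frames whose (φ,ψ) satisfies a region predicate."""

    residue: int
    window: tuple[int, int]
    fraction_in_region: float
    n_frames: int


@dataclass
class BFactorProfile:
    """Per-residue B values (Å²) with their standardized (z-score) profile.

    Standardization uses the population SD, so the standardized profile has
    mean 0 and SD 1 exactly and is invariant under positive affine
    transforms of the raw values — the property that makes profiles from
    crystal structures and simulations comparable.
    """

    values: np.ndarray
    standardized: np.ndarray
    residues: list[int] | None = None


@dataclass
class SubspaceOverlap:
    """RMSIP between the leading covariance eigenspaces of two windows."""

    n_modes: int
    rmsip: float
    eigenvalues_a: np.ndarray
    eigenvalues_b: np.ndarray


def _window_slice(window: tuple[int, int], n_frames: int) -> slice:
    a, b = window
    if not 0 <= a < b <= n_frames:
        raise ValueError(f"window {window} invalid for {n_frames} frames")
    return slice(a, b)


def dihedral_series(traj: Trajectory, residue: int,
                    chain_id: str | None = None) -> list[tuple[float, float]]:
    """(φ, ψ) of one residue for every frame.

    The residue is identified by author number (and optionally chain); it
    must be flanked on both sides so that both dihedrals are defined.
    """
    topo = traj.topology
    cid = chain_id or next(iter(topo.chains))
    residues = topo.polymer_residues(cid)
    idx = next((i for i, r in enumerate(residues) if r.seq_number == residue), None)
    if idx is None:
        raise ValueError(f"residue {residue} not found in chain {cid}")
    if idx == 0 or idx == len(residues) - 1:
        raise ValueError(f"residue {residue} is a chain terminus; (φ,ψ) undefined")
    series: list[tuple[float, float]] = []
    for f in range(traj.n_frames):
        model = traj.frame_model(f)
        rec = next(r for r in backbone_dihedrals(model, cid)
                   if r.residue.seq_number == residue)
        if rec.phi is None or rec.psi is None:
            raise ValueError(f"frame {f}: (φ,ψ) undefined for residue {residue}")
        series.append((rec.phi, rec.psi))
    return series


def region_occupancy(series: list[tuple[float, float]], region_predicate,
                     window: tuple[int, int] | None = None,
                     residue: int = 0) -> OccupancySummary:
    """Fraction of frames in a window whose (φ,ψ) satisfies the predicate."""
    n = len(series)
    if window is None:
        window = (0, n)
    sl = _window_slice(window, n)
    frames = series[sl]
    if not frames:
        raise ValueError("empty window")
    hits = sum(1 for phi, psi in frames if region_predicate(phi, psi))
    return OccupancySummary(residue=residue, window=window,
                            fraction_in_region=hits / len(frames),
                            n_frames=len(frames))


def rmsd_series(traj: Trajectory, reference: np.ndarray | None = None,
                atom_indices: np.ndarray | None = None) -> np.ndarray:
    """Per-frame Cα RMSD (Å) against a reference after optimal superposition.

    reference defaults to the topology coordinates; atom_indices defaults to
    the Cα atoms.
    """
    idx = traj.ca_indices() if atom_indices is None else np.asarray(atom_indices)
    if idx.size < 3:
        raise ValueError("need at least 3 atoms for RMSD superposition")
    ref = (traj.topology.all_coords() if reference is None
           else np.asarray(reference, dtype=float))
    if ref.shape[0] == traj.n_atoms:
        ref = ref[idx]
    elif ref.shape[0] != idx.size:
        raise ValueError("reference does not match the selected atoms")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_rmsd(traj.coords[f, idx], ref)[0]
    return out


def rg_series(traj: Trajectory, atom_indices: np.ndarray | None = None,
              masses: np.ndarray | None = None) -> np.ndarray:
    """Per-frame radius of gyration, Å, with unit masses by default."""
    idx = (np.arange(traj.n_atoms) if atom_indices is None
           else np.asarray(atom_indices))
    if idx.size < 1:
        raise ValueError("need at least one atom for Rg")
    m = np.ones(idx.size) if masses is None else np.asarray(masses, dtype=float)
    if m.shape != (idx.size,):
        raise ValueError("one mass per selected atom required")
    X = traj.coords[:, idx, :]
    com = (X * m[None, :, None]).sum(axis=1) / m.sum()
    d2 = ((X - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((d2 * m[None, :]).sum(axis=1) / m.sum())


def standardized_bfactors(values) -> BFactorProfile:
    """Carugo-style standardized B-factors: z = (B − mean)/SD (population).

    Raises DegenerateProfileError for fewer than 2 residues or a constant
    profile.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DegenerateProfileError("need at least 2 residues to standardize")
    sd = float(v.std())  # population SD
    if sd == 0.0:
        raise DegenerateProfileError("constant B-factor profile cannot be standardized")
    return BFactorProfile(values=v, standardized=(v - v.mean()) / sd)


def _superpose_window(X: np.ndarray) -> np.ndarray:
    """Superpose every frame of X (n_f, n_atoms, 3) onto the window-average
    structure (one refinement iteration), returning the fitted coordinates."""
    mean = X.mean(axis=0)
    fitted = np.empty_like(X)
    for f in range(X.shape[0]):
        _, Rm, t = kabsch_rmsd(X[f], mean)
        fitted[f] = X[f] @ Rm.T + t
    mean2 = fitted.mean(axis=0)
    for f in range(X.shape[0]):
        _, Rm, t = kabsch_rmsd(fitted[f], mean2)
        fitted[f] = fitted[f] @ Rm.T + t
    return fitted


def pseudo_bfactors_from_traj(traj: Trajectory,
                              window: tuple[int, int] | None = None
                              ) -> np.ndarray:
    """Per-residue Cα pseudo B-factors, Å², from window fluctuations.

    B = (8π²/3)·MSF where MSF is the mean squared fluctuation of each Cα
    about its window-mean position after superposing every frame onto the
    window-average structure (rigid-body motion therefore contributes
    nothing).
    """
    idx = traj.ca_indices()
    if idx.size < 3:
        raise ValueError("need at least 3 Cα atoms")
    if window is None:
        window = (0, traj.n_frames)
    sl = _window_slice(window, traj.n_frames)
    X = traj.coords[sl][:, idx, :]
    if X.shape[0] < 2:
        raise ValueError("window must contain at least 2 frames")
    fitted = _superpose_window(X)
    msf = ((fitted - fitted.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
    return EIGHT_PI2 / 3.0 * msf


def rmsip(traj: Trajectory, window_a: tuple[int, int],
          window_b: tuple[int, int], n_modes: int = 10) -> SubspaceOverlap:
    """Root mean square inner product between two windows' Cα subspaces.

    Each window's frames are superposed onto their window-average structure;
    the covariance of the flattened Cα coordinates is eigen-decomposed and
    RMSIP = sqrt((1/n)·ΣΣ (η_a·ν_b)²) over the first n_modes eigenvectors
    of each window. 1 means identical essential subspaces, 0 orthogonal.
    """
    idx = traj.ca_indices()
    sl_a = _window_slice(window_a, traj.n_frames)
    sl_b = _window_slice(window_b, traj.n_frames)
    if max(window_a[0], window_b[0]) < min(window_a[1], window_b[1]):
        warnings.warn("rmsip windows overlap", stacklevel=2)
    evals, evecs = [], []
    for sl in (sl_a, sl_b):
        X = traj.coords[sl][:, idx, :]
        if X.shape[0] < n_modes:
            raise ValueError(f"window of {X.shape[0]} frames cannot support "
                             f"{n_modes} modes")
        fitted = _superpose_window(X)
        flat = fitted.reshape(fitted.shape[0], -1)
        flat = flat - flat.mean(axis=0)
        # right singular vectors of the centred matrix = covariance eigenvectors
        _, s, Vt = np.linalg.svd(flat, full_matrices=False)
        lam = s ** 2 / flat.shape[0]
        evals.append(lam[:n_modes])
        evecs.append(Vt[:n_modes])
    inner = evecs[0] @ evecs[1].T
    val = float(np.sqrt(np.sum(inner ** 2) / n_modes))
    return SubspaceOverlap(n_modes=n_modes, rmsip=min(val, 1.0),
                           eigenvalues_a=evals[0], eigenvalues_b=evals[1])
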