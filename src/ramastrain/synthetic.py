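"""Synthetic inputs with exactly known ground truth.

Everything the analysis pipeline consumes can be generated here: peptides
with exactly specified backbone dihedrals and standard valence geometry
(internal-to-Cartesian chain construction), structure sets with planted
(φ,ψ)-box occupancy and nominal resolutions, trajectories with prescribed
per-residue region occupancy and fluctuation profiles, and noisy two-state
melting curves and DSC thermograms with known Td, ΔH and baselines.

All generators are seed-deterministic: the same seed gives bitwise-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ramastrain.errors import SequenceError
from ramastrain.structures import AtomRecord, ResidueRecord, StructureModel, Trajectory

__all__ = [
    "GeometryTable", "ThermalParams", "build_peptide", "ideal_helix",
    "plant_census_set", "synth_trajectory", "orthogonal_mode_trajectory",
    "synth_melt_curve", "synth_dsc_curve",
    "box_sampler", "quadrant_sampler", "helix_sampler", "ONE_TO_THREE",
]

#: Gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class GeometryTable:
    """Reference backbone bond lengths / valence angles with sigmas.

    Backed by the packaged Engh–Huber-style CSV; lookup falls back from a
    specific residue class (GLY, PRO) to 'other'.
    """

    def __init__(self, rows: dict[tuple[str, str], tuple[float, float]]):
        self._rows = rows

    @classmethod
    def default(cls) -> "GeometryTable":
        text = resources.files("ramastrain").joinpath("data/engh_huber.csv").read_text()
        rows: dict[tuple[str, str], tuple[float, float]] = {}
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.startswith("residue_class"):
                continue
            cls_, param, mean, sigma = ln.split(",")
            mean, sigma = float(mean), float(sigma)
            if not sigma > 0:
                raise ValueError(f"non-positive sigma for {cls_}/{param}")
            rows[(cls_, param)] = (mean, sigma)
        return cls(rows)

    def mean(self, res_class: str, param: str) -> float:
        return self.get(res_class, param)[0]

    def sigma(self, res_class: str, param: str) -> float:
        return self.get(res_class, param)[1]

    def get(self, res_class: str, param: str) -> tuple[float, float]:
        key = (res_class.upper(), param)
        if key in self._rows:
            return self._rows[key]
        if ("other", param) in self._rows:
            return self._rows[("other", param)]
        raise KeyError(f"no reference geometry for {res_class}/{param}")


@dataclass
class ThermalParams:
    """Ground truth for a simulated two-state thermal transition.

    td in °C, dh_cal in kJ/mol; baselines are (intercept, slope) evaluated
    against temperature in °C; noise_sd is in signal units.
    """

    td: float
    dh_cal: float
    native_baseline: tuple[float, float] = (0.0, 0.0)
    denatured_baseline: tuple[float, float] = (1.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.td < 150.0:
            raise ValueError("td must be in (0, 150) °C")
        if not self.dh_cal > 0:
            raise ValueError("dh_cal must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# internal-to-Cartesian peptide construction

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Place atom D from (A, B, C): |CD| = bond, angle(B,C,D) = theta,
    torsion(A,B,C,D) = chi with the package's torsion sign convention."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    b1 = b - a
    b2u = c - b
    b2u = b2u / np.linalg.norm(b2u)
    n = np.cross(b1, b2u)
    n = n / np.linalg.norm(n)
    m = np.cross(n, b2u)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * b2u + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
              bond: float, ang_n_deg: float, ang_c_deg: float) -> np.ndarray:
    """Cβ position satisfying both N–CA–CB and CB–CA–C angles with
    L-amino-acid chirality."""
    u1 = n - ca
    u1 = u1 / np.linalg.norm(u1)
    u2 = c - ca
    u2 = u2 / np.linalg.norm(u2)
    d = float(np.dot(u1, u2))
    cos1 = math.cos(math.radians(ang_n_deg))
    cos2 = math.cos(math.radians(ang_c_deg))
    det = 1.0 - d * d
    a = (cos1 - d * cos2) / det
    b = (cos2 - d * cos1) / det
    w = np.cross(u1, u2)
    w = w / np.linalg.norm(w)
    c2 = 1.0 - (a * a + b * b + 2.0 * a * b * d)
    if c2 < 0:
        c2 = 0.0
    # positive component along u1×u2 gives the L configuration with the
    # N, CA, C ordering used here (verified against the standard idealized
    # Cβ reconstruction).
    v = a * u1 + b * u2 + math.sqrt(c2) * w
    return ca + bond * v


def build_peptide(sequence: str,
                  phi_psi: list[tuple[float | None, float | None]],
                  omega: list[float] | None = None,
                  geometry: GeometryTable | None = None,
                  chain_id: str = "A",
                  start_number: int = 1,
                  angle_overrides: dict[tuple[int, str], float] | None = None,
                  b_factors: list[float] | None = None,
                  structure_id: str = "synthetic-peptide") -> StructureModel:
    """Build a peptide with exactly the requested (φ, ψ, ω).

    Atoms are placed sequentially, each from one bond length, one valence
    angle and one torsion taken from the reference GeometryTable (per
    residue class), so measured dihedrals of the result equal the request to
    1e-6° and measured valence angles equal the table. Backbone atoms
    N, CA, C, O are built for every residue plus a tetrahedral Cβ for
    non-Gly; φ of the first and ψ of the last residue are ignored
    (undefined). ω defaults to 180° (trans) everywhere.

    angle_overrides maps (0-based residue index, parameter name) to a value
    replacing the table entry for that residue only — the hook for building
    strained fixtures (e.g. an NCaCb inflated by k·σ).
    """
    n = len(sequence)
    if n < 1:
        raise SequenceError("empty sequence")
    if len(phi_psi) != n:
        raise ValueError(f"phi_psi length {len(phi_psi)} != sequence length {n}")
    if omega is None:
        omega = [180.0] * n
    if len(omega) != n:
        raise ValueError(f"omega length {len(omega)} != sequence length {n}")
    for i, w in enumerate(omega):
        if i > 0 and w is not None and not -180.0 < w <= 180.0:
            raise ValueError(f"omega[{i}] = {w} outside (-180, 180]")
    bad = [ch for ch in sequence if ch.upper() not in ONE_TO_THREE]
    if bad:
        raise SequenceError(f"unknown residue letter(s): {''.join(sorted(set(bad)))}")
    geometry = geometry or GeometryTable.default()
    overrides = angle_overrides or {}

    res_names = [ONE_TO_THREE[ch.upper()] for ch in sequence]

    def par(i: int, name: str) -> float:
        if (i, name) in overrides:
            return overrides[(i, name)]
        return geometry.mean(res_names[i], name)

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))

    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (par(0, "N_CA"), 0.0, 0.0)
    ang = math.radians(par(0, "NCaC"))
    u = (N[0] - CA[0]) / np.linalg.norm(N[0] - CA[0])
    v = math.cos(ang) * u + math.sin(ang) * np.array([0.0, 1.0, 0.0])
    C[0] = CA[0] + par(0, "CA_C") * v

    for i in range(n - 1):
        psi = phi_psi[i][1]
        if psi is None:
            raise ValueError(f"psi of residue {i} is required to chain residue {i + 1}")
        N[i + 1] = _nerf(N[i], CA[i], C[i], par(i, "C_N"),
                         par(i, "CaCN_next"), psi)
        w = omega[i + 1] if omega[i + 1] is not None else 180.0
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], par(i + 1, "N_CA"),
                          par(i + 1, "Cprev_N_Ca"), w)
        phi = phi_psi[i + 1][0]
        if phi is None:
            raise ValueError(f"phi of residue {i + 1} is required (only the "
                             "first residue's phi is undefined)")
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], par(i + 1, "CA_C"),
                         par(i + 1, "NCaC"), phi)
        O[i] = _nerf(N[i], CA[i], C[i], par(i, "C_O"), par(i, "CaCO"),
                     _wrap(psi + 180.0))
    # carbonyl O of the last residue: psi is undefined there, an anti
    # placement relative to N is used
    psi_last = phi_psi[n - 1][1]
    psi_eff = psi_last if psi_last is not None else 180.0
    O[n - 1] = _nerf(N[n - 1], CA[n - 1], C[n - 1], par(n - 1, "C_O"),
                     par(n - 1, "CaCO"), _wrap(psi_eff + 180.0))

    residues: list[ResidueRecord] = []
    for i, rn in enumerate(res_names):
        b = 0.0 if b_factors is None else float(b_factors[i])
        atoms = [
            AtomRecord("N", "N", N[i], 1.0, b),
            AtomRecord("CA", "C", CA[i], 1.0, b),
            AtomRecord("C", "C", C[i], 1.0, b),
            AtomRecord("O", "O", O[i], 1.0, b),
        ]
        if rn != "GLY":
            cb = _place_cb(N[i], CA[i], C[i], par(i, "CA_CB"),
                           par(i, "NCaCb"), par(i, "CbCaC"))
            atoms.append(AtomRecord("CB", "C", cb, 1.0, b))
        residues.append(ResidueRecord(chain_id, start_number + i, "", rn, atoms))
    return StructureModel(structure_id=structure_id, model_number=1,
                          chains={chain_id: residues})


def _wrap(a: float) -> float:
    a = math.remainder(a, 360.0)
    return 180.0 if a == -180.0 else a


# ---------------------------------------------------------------------------
# planted census sets

def plant_census_set(n_structures: int,
                     per_structure_length: int,
                     planted: list[tuple[str, float, float, int]],
                     resolutions: list[float | None],
                     seed: int = 0) -> list[StructureModel]:
    """Structure set with exactly known (φ,ψ)-box occupancy.

    planted is a list of (res_class, φ, ψ, count) with res_class 'GLY' or
    'nonGLY'; exactly count residues of that class are placed at (φ, ψ),
    scattered deterministically (by seed) over interior positions of the
    set. All other residues are alanines in a canonical α-helical
    conformation (−57, −47). resolutions (one per structure, None allowed)
    are attached as header resolution.
    """
    if len(resolutions) != n_structures:
        raise ValueError("need one resolution per structure")
    if any(cnt < 0 for _, _, _, cnt in planted):
        raise ValueError("planted counts must be >= 0")
    interior = per_structure_length - 2
    capacity = n_structures * interior
    total = sum(cnt for _, _, _, cnt in planted)
    if total > capacity:
        raise ValueError(f"planted count {total} exceeds capacity {capacity}")
    rng = np.random.default_rng(seed)
    slots = [(s, p) for s in range(n_structures) for p in range(1, interior + 1)]
    order = rng.permutation(len(slots))
    assignments: dict[tuple[int, int], tuple[str, float, float]] = {}
    k = 0
    for res_class, phi, psi, cnt in planted:
        if res_class not in ("GLY", "nonGLY"):
            raise ValueError(f"res_class must be GLY or nonGLY, got {res_class}")
        letter = "G" if res_class == "GLY" else "A"
        for _ in range(cnt):
            s, p = slots[order[k]]
            assignments[(s, p)] = (letter, phi, psi)
            k += 1
    models = []
    for s in range(n_structures):
        seq = []
        phi_psi: list[tuple[float, float]] = []
        for p in range(per_structure_length):
            if (s, p) in assignments:
                letter, phi, psi = assignments[(s, p)]
            else:
                letter, phi, psi = "A", -57.0, -47.0
            seq.append(letter)
            phi_psi.append((phi, psi))
        model = build_peptide("".join(seq), phi_psi,
                              structure_id=f"planted-{s:04d}")
        model.resolution = resolutions[s]
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# trajectories

def box_sampler(center_phi: float, center_psi: float, width: float = 10.0):
    """Sampler drawing (φ,ψ) uniformly inside a square box."""
    def sample(rng: np.random.Generator) -> tuple[float, float]:
        half = width / 2.0
        return (center_phi + rng.uniform(-half, half),
                center_psi + rng.uniform(-half, half))
    return sample


def quadrant_sampler(margin: float = 5.0):
    """Sampler drawing uniformly inside the forbidden quadrant
    φ ∈ [90, 180], ψ ∈ [−180, −80] (shrunk by a safety margin)."""
    def sample(rng: np.random.Generator) -> tuple[float, float]:
        return (rng.uniform(90.0 + margin, 180.0 - margin),
                rng.uniform(-180.0 + margin, -80.0 - margin))
    return sample


def helix_sampler(spread: float = 8.0):
    """Sampler around the canonical α-helical conformation (−57, −47)."""
    def sample(rng: np.random.Generator) -> tuple[float, float]:
        return (-57.0 + rng.uniform(-spread, spread),
                -47.0 + rng.uniform(-spread, spread))
    return sample


def synth_trajectory(n_frames: int,
                     template: StructureModel,
                     target_residue: int | None = None,
                     occupancy_plan: list[tuple] | None = None,
                     fluctuation_profile: np.ndarray | list[float] | None = None,
                     seed: int = 0,
                     template_dihedrals: list[tuple[float, float]] | None = None,
                     ) -> Trajectory:
    """Trajectory with prescribed target-residue occupancy and fluctuations.

    template must be a single-chain peptide built by :func:`build_peptide`
    (the frames are re-built from dihedrals, so the builder's atom inventory
    is required). occupancy_plan is a list of (sampler, fraction) pairs;
    each frame first picks a plan entry with the given probability, then
    draws the target residue's (φ,ψ) from that sampler, so the empirical
    fraction of frames per region is binomial around the plan. Remaining
    residues keep the template conformation. Independent Gaussian
    displacements with per-residue σ (fluctuation_profile, Å) are added to
    every atom afterwards.

    template_dihedrals, when given, supplies the template's (φ,ψ) list and
    skips re-measuring it (the builder's round-trip makes both equivalent).
    """
    from ramastrain.geometry import backbone_dihedrals

    chain_id = next(iter(template.chains))
    residues = template.polymer_residues(chain_id)
    n_res = len(residues)
    if fluctuation_profile is None:
        sigma = np.zeros(n_res)
    else:
        sigma = np.asarray(fluctuation_profile, dtype=float)
        if sigma.shape != (n_res,):
            raise ValueError("fluctuation_profile must have one σ per residue")
        if np.any(sigma < 0):
            raise ValueError("fluctuation σ must be >= 0")
    if occupancy_plan is not None:
        fracs = np.array([f for _, f in occupancy_plan], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy plan fractions must sum to 1")
        if target_residue is None:
            raise ValueError("occupancy plan requires a target residue")
    target_idx = None
    if target_residue is not None:
        target_idx = next((i for i, r in enumerate(residues)
                           if r.seq_number == target_residue), None)
        if target_idx is None:
            raise ValueError(f"target residue {target_residue} not in template")
        if target_idx in (0, n_res - 1):
            raise ValueError("target residue must not be a terminus")

    if template_dihedrals is None:
        recs = backbone_dihedrals(template, chain_id)
        template_dihedrals = [(r.phi, r.psi) for r in recs]
    sequence = "".join(_three_to_one(r.res_name) for r in residues)
    start = residues[0].seq_number

    rng = np.random.default_rng(seed)
    n_atoms = template.atom_count()
    atom_res = np.array([ri for ri, r in enumerate(residues) for _ in r.atoms])
    coords = np.empty((n_frames, n_atoms, 3))
    base = template.all_coords()
    for f in range(n_frames):
        if occupancy_plan is not None:
            entry = rng.choice(len(occupancy_plan), p=fracs)
            sampler = occupancy_plan[entry][0]
            phi, psi = sampler(rng)
            dihed = list(template_dihedrals)
            dihed[target_idx] = (phi, psi)
            frame_model = build_peptide(sequence, dihed, chain_id=chain_id,
                                        start_number=start)
            frame = frame_model.all_coords()
        else:
            frame = base.copy()
        if np.any(sigma > 0):
            frame = frame + rng.normal(0.0, 1.0, size=(n_atoms, 3)) * \
                sigma[atom_res][:, None]
        coords[f] = frame
    return Trajectory(topology=template, coords=coords)


def ideal_helix(n: int = 15, sequence: str | None = None) -> StructureModel:
    """Ideal α-helix at (φ, ψ) = (−57, −47), all-trans."""
    sequence = sequence or "A" * n
    plan = [(None, -47.0)] + [(-57.0, -47.0)] * (n - 2) + [(-57.0, None)]
    return build_peptide(sequence, plan, structure_id="ideal-helix")


def orthogonal_mode_trajectory(n_modes: int = 4, n_frames: int = 40,
                               amplitude: float = 1e-3, seed: int = 17
                               ) -> tuple[Trajectory, int, int]:
    """Trajectory whose two halves fluctuate in orthogonal internal
    subspaces — ground truth for subspace-overlap (RMSIP) statistics.

    2·n_modes random Cα displacement patterns are projected off the six
    rigid-body modes of the base structure and orthonormalised; frames of
    the first half excite only the first n_modes patterns, the second half
    only the rest, so the covariance eigenspaces of the halves are exactly
    orthogonal (RMSIP 0) while each half against itself gives RMSIP 1.
    Returns (trajectory, n_modes, frames per half).
    """
    rng = np.random.default_rng(seed)
    model = ideal_helix(12)
    base = model.all_coords()
    ca_idx = [i for i, (r, _, a) in enumerate(model.iter_atoms())
              if a.name == "CA"]
    ca = base[ca_idx]
    centred = ca - ca.mean(axis=0)
    rigid = []
    for k in range(3):
        t = np.zeros_like(ca)
        t[:, k] = 1.0
        rigid.append(t.ravel())
    for axis in np.eye(3):
        rigid.append(np.cross(np.broadcast_to(axis, centred.shape),
                              centred).ravel())
    rigid = np.linalg.qr(np.array(rigid).T)[0].T
    raw = rng.normal(size=(2 * n_modes, ca.size))
    raw -= (raw @ rigid.T) @ rigid
    patterns = np.linalg.qr(raw.T)[0].T
    coords = np.repeat(base[None], 2 * n_frames, axis=0)
    for f in range(2 * n_frames):
        block = patterns[:n_modes] if f < n_frames else patterns[n_modes:]
        amps = rng.normal(0.0, amplitude, n_modes)
        coords[f, ca_idx] = coords[f, ca_idx] + (amps @ block).reshape(-1, 3)
    return Trajectory(topology=model, coords=coords), n_modes, n_frames


def _three_to_one(name: str) -> str:
    inv = {v: k for k, v in ONE_TO_THREE.items()}
    try:
        return inv[name.upper()]
    except KeyError:
        raise SequenceError(f"no one-letter code for residue {name}") from None


# ---------------------------------------------------------------------------
# thermal curves

def _two_state_K(t_c: np.ndarray, td_c: float, dh_kj: float) -> np.ndarray:
    """Equilibrium constant of the N ↔ D transition.

    K(T) = exp[−(ΔH/R)(1/T − 1/Td)] with temperatures in kelvin; K(Td) = 1
    and K grows with temperature for ΔH > 0.
    """
    T = np.asarray(t_c, dtype=float) + 273.15
    Td = td_c + 273.15
    return np.exp(-(dh_kj * 1e3 / R_GAS) * (1.0 / T - 1.0 / Td))


def _check_grid(t_grid: np.ndarray, td: float) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not t[0] < td < t[-1]:
        raise ValueError(f"td {td} °C outside grid [{t[0]}, {t[-1]}]")
    return t


def synth_melt_curve(params: ThermalParams, t_grid):
    """Two-state melting curve with linear baselines and Gaussian noise.

    signal(T) = [θ_N(T) + θ_D(T)·K(T)] / (1 + K(T)); at T = Td the signal
    is the exact midpoint of the two baselines. Returns a
    :class:`~ramastrain.thermal.MeltCurve`.
    """
    from ramastrain.thermal import MeltCurve

    t = _check_grid(t_grid, params.td)
    K = _two_state_K(t, params.td, params.dh_cal)
    aN, bN = params.native_baseline
    aD, bD = params.denatured_baseline
    theta_n = aN + bN * t
    theta_d = aD + bD * t
    signal = (theta_n + theta_d * K) / (1.0 + K)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        signal = signal + rng.normal(0.0, params.noise_sd, size=t.shape)
    return MeltCurve(temperature=t, signal=signal)


def synth_dsc_curve(params: ThermalParams, t_grid):
    """Two-state excess heat capacity plus native baseline and noise.

    ΔC_p(T) = ΔH²·K / (R·T²·(1+K)²) in kJ mol⁻¹ K⁻¹ (T kelvin), the exact
    van't Hoff two-state peak: its maximum sits at Td and its integral is
    ΔH. The native baseline (params.native_baseline, in kJ mol⁻¹ K⁻¹ vs
    °C) is added on top, as in a raw thermogram after buffer subtraction.
    Returns a :class:`~ramastrain.thermal.Thermogram`.
    """
    from ramastrain.thermal import Thermogram

    t = _check_grid(t_grid, params.td)
    T = t + 273.15
    K = _two_state_K(t, params.td, params.dh_cal)
    dh_j = params.dh_cal * 1e3
    cp_excess_j = dh_j ** 2 * K / (R_GAS * T ** 2 * (1.0 + K) ** 2)
    aN, bN = params.native_baseline
    cp = cp_excess_j / 1e3 + aN + bN * t
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        cp = cp + rng.normal(0.0, params.noise_sd, size=t.shape)
    return Thermogram(temperature=t, cp_excess=cp)
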