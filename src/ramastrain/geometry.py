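"""Backbone geometry: dihedrals, valence angles, strain contacts, RMSD.

All angles are reported in degrees in the half-open range (−180, 180], with
an exact −180 mapped to +180. Torsions follow the IUPAC convention: the
eclipsed (cis) arrangement is 0° and the sign is given by the right-handed
rule about the central bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ramastrain.errors import GeometryError
from ramastrain.structures import ResidueRecord, StructureModel, chain_break

__all__ = [
    "DihedralRecord", "BondAngleSet", "ContactPair",
    "wrap_angle", "dihedral", "bond_angle", "backbone_dihedrals",
    "delta_omega", "valence_angles", "cb_contact_distances",
    "kabsch_rmsd", "surrounding_contacts",
]

#: Default flagging threshold for Cβ strain contacts, Å. Sum of the C/N and
#: C/O van der Waals contact distances minus a 0.2 Å tolerance.
STRAIN_CONTACT_THRESHOLD = 3.1

#: The seven monitored valence angles plus the Cβ angle; keys of
#: BondAngleSet.angles.
MONITORED_ANGLES = ("NCaC", "NCaCb", "CbCaC", "CaCO", "CaCN_next",
                    "OCN_next", "Cprev_N_Ca")


def wrap_angle(angle: float) -> float:
    """Wrap into (−180, 180]; exact −180 maps to +180."""
    a = math.remainder(angle, 360.0)
    return 180.0 if a == -180.0 else a


@dataclass
class DihedralRecord:
    """(φ, ψ, ω) of one residue; None marks chain termini and breaks."""

    residue: ResidueRecord
    phi: float | None
    psi: float | None
    omega: float | None

    @property
    def rid(self) -> tuple[str, int, str]:
        return self.residue.rid


@dataclass
class BondAngleSet:
    """The monitored backbone valence angles of one residue, degrees.

    angles maps the keys in MONITORED_ANGLES to values (None where atoms
    are absent, e.g. NCaCb/CbCaC for Gly); delta_omega is the signed
    peptide-planarity deviation of the residue's own ω.
    """

    residue: ResidueRecord
    angles: dict[str, float | None] = field(default_factory=dict)
    delta_omega: float | None = None


@dataclass
class ContactPair:
    """A distance between two atoms identified by (residue label, atom name)."""

    atom_a: tuple[str, str]
    atom_b: tuple[str, str]
    distance: float


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError(f"degenerate geometry: zero-length {what}")
    return v / n


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1–p2–p3–p4 in degrees, IUPAC sign, range (−180, 180].

    Raises GeometryError when p1p2p3 or p2p3p4 are collinear or consecutive
    points coincide.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b, name in ((b1, "bond p1-p2"), (b2, "bond p2-p3"), (b3, "bond p3-p4")):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError(f"degenerate geometry: coincident points ({name})")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("degenerate geometry: collinear points")
    b2u = _unit(b2, "central bond")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Valence angle at p2, degrees in (0, 180)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = _unit(p1 - p2, "bond p1-p2")
    v = _unit(p3 - p2, "bond p3-p2")
    return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


def delta_omega(omega: float | None) -> float | None:
    """Signed deviation of ω from the nearer planar ideal, in (−90, 90].

    trans (|ω| > 90) is referenced to 180°, cis to 0°; the deviation wraps
    through ±180 (ω = −178 → +2).
    """
    if omega is None:
        return None
    w = wrap_angle(omega)
    if abs(w) > 90.0:
        return wrap_angle(w - 180.0)
    return w


def backbone_dihedrals(model: StructureModel,
                       chain_id: str | None = None) -> list[DihedralRecord]:
    """Per-residue (φ, ψ, ω) over the polymer residues of a model.

    φ_i = C_{i−1}–N_i–CA_i–C_i, ψ_i = N_i–CA_i–C_i–N_{i+1},
    ω_i = CA_{i−1}–C_{i−1}–N_i–CA_i. Fields are None at chain termini and
    across chain breaks (missing atoms or a C–N peptide distance > 2.5 Å).
    """
    out: list[DihedralRecord] = []
    chain_ids = [chain_id] if chain_id is not None else list(model.chains)
    for cid in chain_ids:
        residues = model.polymer_residues(cid)
        n = len(residues)
        for i, res in enumerate(residues):
            prev = residues[i - 1] if i > 0 else None
            nxt = residues[i + 1] if i < n - 1 else None
            linked_prev = prev is not None and not chain_break(prev, res)
            linked_next = nxt is not None and not chain_break(res, nxt)
            phi = psi = omega = None
            N, CA, C = res.coord("N"), res.coord("CA"), res.coord("C")
            if N is not None and CA is not None and C is not None:
                if linked_prev and prev.coord("C") is not None:
                    try:
                        phi = dihedral(prev.coord("C"), N, CA, C)
                    except GeometryError:
                        phi = None
                if linked_prev and prev.coord("CA") is not None and prev.coord("C") is not None:
                    try:
                        omega = dihedral(prev.coord("CA"), prev.coord("C"), N, CA)
                    except GeometryError:
                        omega = None
                if linked_next and nxt.coord("N") is not None:
                    try:
                        psi = dihedral(N, CA, C, nxt.coord("N"))
                    except GeometryError:
                        psi = None
            out.append(DihedralRecord(res, phi, psi, omega))
    return out


def valence_angles(model: StructureModel, residue: ResidueRecord) -> BondAngleSet:
    """The monitored valence angles of one residue.

    Angles whose atoms are absent (Cβ angles for Gly, next-residue angles at
    the C-terminus, Cprev_N_Ca at the N-terminus or across a break) are None.
    """
    residues = model.polymer_residues(residue.chain_id)
    try:
        idx = next(i for i, r in enumerate(residues) if r.rid == residue.rid)
    except StopIteration:
        raise ValueError(f"residue {residue.label} not found in model") from None
    prev = residues[idx - 1] if idx > 0 else None
    nxt = residues[idx + 1] if idx < len(residues) - 1 else None
    if prev is not None and chain_break(prev, residue):
        prev = None
    if nxt is not None and chain_break(residue, nxt):
        nxt = None

    N, CA, C = residue.coord("N"), residue.coord("CA"), residue.coord("C")
    O, CB = residue.coord("O"), residue.coord("CB")
    n_next = nxt.coord("N") if nxt is not None else None

    def safe(*pts):
        if any(p is None for p in pts):
            return None
        try:
            return bond_angle(*pts)
        except GeometryError:
            return None

    angles = {
        "NCaC": safe(N, CA, C),
        "NCaCb": safe(N, CA, CB),
        "CbCaC": safe(CB, CA, C),
        "CaCO": safe(CA, C, O),
        "CaCN_next": safe(CA, C, n_next),
        "OCN_next": safe(O, C, n_next),
        "Cprev_N_Ca": safe(prev.coord("C") if prev else None, N, CA),
    }
    omega = None
    if prev is not None and all(
            p is not None for p in (prev.coord("CA"), prev.coord("C"), N, CA)):
        try:
            omega = dihedral(prev.coord("CA"), prev.coord("C"), N, CA)
        except GeometryError:
            omega = None
    return BondAngleSet(residue=residue, angles=angles,
                        delta_omega=delta_omega(omega))


def cb_contact_distances(model: StructureModel, residue: ResidueRecord
                         ) -> tuple[float | None, float | None]:
    """Distances Cβ(i)–O(i−1) and Cβ(i)–N(i+1), Å.

    These are the two steric-strain contacts that make the lower-right
    Ramachandran quadrant forbidden to residues carrying a Cβ. Either value
    is None when the residue has no Cβ (Gly) or the neighbour atom is
    absent / across a chain break.
    """
    cb = residue.coord("CB")
    if cb is None:
        return (None, None)
    residues = model.polymer_residues(residue.chain_id)
    idx = next((i for i, r in enumerate(residues) if r.rid == residue.rid), None)
    if idx is None:
        raise ValueError(f"residue {residue.label} not found in model")
    d_prev = d_next = None
    if idx > 0 and not chain_break(residues[idx - 1], residue):
        o_prev = residues[idx - 1].coord("O")
        if o_prev is not None:
            d_prev = float(np.linalg.norm(cb - o_prev))
    if idx < len(residues) - 1 and not chain_break(residue, residues[idx + 1]):
        n_next = residues[idx + 1].coord("N")
        if n_next is not None:
            d_next = float(np.linalg.norm(cb - n_next))
    return (d_prev, d_next)


def kabsch_rmsd(coords_a, coords_b) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition of A onto B (proper rotation only).

    Returns (rmsd, rotation, translation) such that A @ rotation.T +
    translation best matches B. A mirror-image pair therefore keeps a
    positive RMSD.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate sets must match in shape, got {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    A_fit = A0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((A_fit - B0) ** 2, axis=1))))
    t = cb - ca @ R.T
    return rmsd, R, t


def match_ca_coords(model_a: StructureModel, model_b: StructureModel
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    """Cα coordinate pairs over the residues shared by author numbering."""
    ca_a = {r.rid: r.coord("CA") for r in model_a.polymer_residues()
            if r.coord("CA") is not None}
    ca_b = {r.rid: r.coord("CA") for r in model_b.polymer_residues()
            if r.coord("CA") is not None}
    common = sorted(set(ca_a) & set(ca_b))
    if not common:
        raise ValueError("no common author-numbered residues with CA atoms")
    A = np.array([ca_a[k] for k in common])
    B = np.array([ca_b[k] for k in common])
    return A, B, common


def surrounding_contacts(model: StructureModel, residue: ResidueRecord,
                         atom_name: str, radius: float,
                         exclude: set[tuple[str, int, str, str]] | None = None
                         ) -> list[ContactPair]:
    """Non-hydrogen atoms within radius of one atom, sorted by distance.

    Excluded from the scan: the residue's own atoms, the probe atom's
    covalently adjacent backbone atoms within three bonds (for a Cβ probe
    the preceding carbonyl carbon and the following amide nitrogen — the
    standard 1-4 clash-scan exclusion), the two Cβ strain partners O(i−1)
    and N(i+1), and any (chain, seqnum, icode, atom name) keys passed in
    ``exclude``. Waters and hetero-atoms (ligands) remain visible.
    """
    probe = residue.coord(atom_name)
    if probe is None:
        raise ValueError(f"residue {residue.label} has no atom {atom_name}")
    excl: set[tuple[str, int, str, str]] = set(exclude or ())
    if atom_name == "CB":
        residues = model.polymer_residues(residue.chain_id)
        idx = next((i for i, r in enumerate(residues) if r.rid == residue.rid), None)
        if idx is not None:
            if idx > 0 and not chain_break(residues[idx - 1], residue):
                prev = residues[idx - 1]
                excl.add((*prev.rid, "O"))
                excl.add((*prev.rid, "C"))
            if idx < len(residues) - 1 and not chain_break(residue, residues[idx + 1]):
                excl.add((*residues[idx + 1].rid, "N"))
    hits: list[ContactPair] = []
    for other in model.residues():
        if other.rid == residue.rid:
            continue
        for a in other.atoms:
            if a.is_hydrogen:
                continue
            if (*other.rid, a.name) in excl:
                continue
            d = float(np.linalg.norm(a.coords - probe))
            if d <= radius:
                hits.append(ContactPair(
                    atom_a=(residue.label, atom_name),
                    atom_b=(other.label, a.name),
                    distance=d))
    hits.sort(key=lambda c: (c.distance, c.atom_b))
    return hits
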