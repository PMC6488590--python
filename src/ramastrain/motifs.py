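"""Geometric H-bond detection, helix-insertion motifs, and strain reports.

A helix-insertion motif is a polypeptide segment inserted within an α-helix
and locked by two consecutive backbone C=O···H-N hydrogen bonds between the
flanking helix residues: donors j and j+1 bond back to acceptors i and i+1,
the inserted region runs i+2 … j−2, and the residue j−1 immediately
preceding the first locking donor is the C0 position — typically a glycine
whose backbone sits in a region forbidden to Cβ-bearing residues.

Crystal structures rarely contain hydrogens, so H-bonds are detected with
the standard heavy-atom geometric proxy: N···O distance and C=O···N angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ramastrain.geometry import (
    STRAIN_CONTACT_THRESHOLD, MONITORED_ANGLES, bond_angle,
    backbone_dihedrals, cb_contact_distances, valence_angles, ContactPair,
)
from ramastrain.rama import BoxSpec, forbidden_quadrant, procheck_region
from ramastrain.structures import ResidueRecord, StructureModel
from ramastrain.synthetic import GeometryTable

__all__ = ["HBond", "MotifHit", "StrainReport",
           "find_hbonds", "find_helix_insertions", "strain_report"]


@dataclass(frozen=True)
class HBond:
    """A backbone N–H···O=C hydrogen bond (heavy-atom criterion).

    donor / acceptor are (chain, seq number, insertion code) of the residues
    providing the amide N and the carbonyl O respectively.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance: float
    angle: float

    @property
    def key(self) -> tuple:
        return (self.donor, self.acceptor)


@dataclass
class MotifHit:
    """One detected helix-insertion motif.

    lock_pair_1 / lock_pair_2 are the two consecutive locking H-bonds as
    (donor rid, acceptor rid); insertion_range spans the inserted residues
    i+2 … j−2 inclusive; c0 is the residue preceding the first donor
    (j−1); c0_helix_hbond records whether the C0 carbonyl accepts the
    helical H-bond from C0+4.
    """

    lock_pair_1: tuple[tuple, tuple]
    lock_pair_2: tuple[tuple, tuple]
    insertion_range: tuple[int, int]
    insertion_length: int
    c0: tuple[str, int, str]
    c0_helix_hbond: bool

    @property
    def acceptors(self) -> tuple[int, int]:
        return (self.lock_pair_1[1][1], self.lock_pair_2[1][1])

    @property
    def donors(self) -> tuple[int, int]:
        return (self.lock_pair_1[0][1], self.lock_pair_2[0][1])

    def as_dict(self) -> dict:
        return {
            "acceptor_1": self.lock_pair_1[1][1],
            "acceptor_2": self.lock_pair_2[1][1],
            "donor_1": self.lock_pair_1[0][1],
            "donor_2": self.lock_pair_2[0][1],
            "insertion_start": self.insertion_range[0],
            "insertion_end": self.insertion_range[1],
            "insertion_length": self.insertion_length,
            "c0": self.c0[1],
            "c0_helix_hbond": self.c0_helix_hbond,
        }


@dataclass
class StrainReport:
    """Conformation-aware strain summary for one residue.

    z_scores compare the monitored valence angles to the reference table;
    outlier_flags mark |z| ≥ threshold; cb_contacts lists the two Cβ strain
    distances (O(i−1), N(i+1)) with their below-threshold flags.
    """

    residue: ResidueRecord
    z_scores: dict[str, float | None]
    outlier_flags: dict[str, bool]
    z_threshold: float
    delta_omega: float | None
    cb_contacts: list[ContactPair]
    cb_strained: list[bool]
    rama_class: str
    in_forbidden_quadrant: bool
    phi: float | None
    psi: float | None

    def as_dict(self) -> dict:
        return {
            "residue": self.residue.label,
            "phi": self.phi, "psi": self.psi,
            "z_scores": self.z_scores,
            "outlier_flags": self.outlier_flags,
            "z_threshold": self.z_threshold,
            "delta_omega": self.delta_omega,
            "cb_contacts": [
                {"partner": c.atom_b, "distance": c.distance, "strained": s}
                for c, s in zip(self.cb_contacts, self.cb_strained)
            ],
            "rama_class": self.rama_class,
            "in_forbidden_quadrant": self.in_forbidden_quadrant,
        }


def find_hbonds(model: StructureModel, cutoff_distance: float = 3.5,
                min_angle: float = 120.0) -> list[HBond]:
    """Backbone–backbone H-bonds by the heavy-atom geometric criterion.

    A donor amide N and acceptor carbonyl O form an H-bond when
    N···O ≤ cutoff_distance and the C=O···N angle ≥ min_angle, with a
    sequence separation |i−j| ≥ 2 within a chain (prolines, which carry no
    amide hydrogen, never donate). The list is ordered by (donor, acceptor).
    """
    donors: list[tuple[ResidueRecord, int, np.ndarray]] = []
    acceptors: list[tuple[ResidueRecord, int, np.ndarray, np.ndarray]] = []
    for cid in model.chains:
        residues = model.polymer_residues(cid)
        for pos, r in enumerate(residues):
            n = r.coord("N")
            if n is not None and r.res_name != "PRO":
                donors.append((r, pos, n))
            o, c = r.coord("O"), r.coord("C")
            if o is not None and c is not None:
                acceptors.append((r, pos, o, c))
    bonds: list[HBond] = []
    for dres, dpos, n in donors:
        for ares, apos, o, c in acceptors:
            if dres.chain_id == ares.chain_id and abs(dpos - apos) < 2:
                continue
            d = float(np.linalg.norm(n - o))
            if d > cutoff_distance:
                continue
            ang = bond_angle(c, o, n)
            if ang < min_angle:
                continue
            bonds.append(HBond(donor=dres.rid, acceptor=ares.rid,
                               distance=d, angle=ang))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def find_helix_insertions(model: StructureModel, hbonds: list[HBond],
                          min_span: int = 6) -> list[MotifHit]:
    """Helix-insertion motifs from an H-bond list.

    Every pair of H-bonds (j→i) and (j+1→i+1) with j − i ≥ min_span yields
    one hit (positions counted along the polymer chain): the two bonds are
    the consecutive C=O···H-N locks, the insertion is i+2 … j−2
    (length j − i − 3), and C0 = j − 1. min_span = 6 (insertion length
    ≥ 3) excludes canonical α-helical i→i+4 bonds and tight turns. Hits
    are sorted by the first acceptor.
    """
    keys = {b.key for b in hbonds}
    hits: list[MotifHit] = []
    for cid in model.chains:
        residues = model.polymer_residues(cid)
        pos_of = {r.rid: p for p, r in enumerate(residues)}
        chain_bonds = [b for b in hbonds
                       if b.donor[0] == cid and b.acceptor[0] == cid
                       and b.donor in pos_of and b.acceptor in pos_of]
        for b in chain_bonds:
            i = pos_of[b.acceptor]
            j = pos_of[b.donor]
            if j - i < min_span:
                continue
            if j + 1 >= len(residues) or i + 1 >= len(residues):
                continue
            second = (residues[j + 1].rid, residues[i + 1].rid)
            if second not in keys:
                continue
            c0 = residues[j - 1]
            helical = False
            if j - 1 + 4 < len(residues):
                helical = (residues[j - 1 + 4].rid, c0.rid) in keys
            hits.append(MotifHit(
                lock_pair_1=(b.donor, b.acceptor),
                lock_pair_2=second,
                insertion_range=(residues[i + 2].seq_number,
                                 residues[j - 2].seq_number),
                insertion_length=j - i - 3,
                c0=c0.rid,
                c0_helix_hbond=helical,
            ))
    hits.sort(key=lambda h: h.lock_pair_1[1])
    return hits


def strain_report(model: StructureModel, residue: ResidueRecord,
                  geometry: GeometryTable | None = None,
                  z_threshold: float = 3.0,
                  strain_cutoff: float = STRAIN_CONTACT_THRESHOLD,
                  box: BoxSpec = BoxSpec()) -> StrainReport:
    """Valence-geometry z-scores, peptide planarity, Cβ strain contacts and
    Ramachandran class for one residue.

    z = (observed − reference mean)/σ per monitored angle against the
    reference GeometryTable (conformation-independent means by default);
    angles whose atoms are absent (Cβ entries for Gly) stay undefined.
    """
    geometry = geometry or GeometryTable.default()
    angle_set = valence_angles(model, residue)
    z_scores: dict[str, float | None] = {}
    flags: dict[str, bool] = {}
    for name in MONITORED_ANGLES:
        obs = angle_set.angles.get(name)
        if obs is None:
            z_scores[name] = None
            flags[name] = False
            continue
        mean, sigma = geometry.get(residue.res_name, name)
        z = (obs - mean) / sigma
        z_scores[name] = z
        flags[name] = abs(z) >= z_threshold
    if angle_set.delta_omega is not None:
        _, sig_w = geometry.get(residue.res_name, "delta_omega")
        z_scores["delta_omega"] = angle_set.delta_omega / sig_w
        flags["delta_omega"] = abs(z_scores["delta_omega"]) >= z_threshold
    else:
        z_scores["delta_omega"] = None
        flags["delta_omega"] = False

    d_prev, d_next = cb_contact_distances(model, residue)
    contacts: list[ContactPair] = []
    strained: list[bool] = []
    residues = model.polymer_residues(residue.chain_id)
    idx = next((k for k, r in enumerate(residues) if r.rid == residue.rid), None)
    if d_prev is not None and idx is not None and idx > 0:
        contacts.append(ContactPair((residue.label, "CB"),
                                    (residues[idx - 1].label, "O"), d_prev))
        strained.append(d_prev < strain_cutoff)
    if d_next is not None and idx is not None and idx < len(residues) - 1:
        contacts.append(ContactPair((residue.label, "CB"),
                                    (residues[idx + 1].label, "N"), d_next))
        strained.append(d_next < strain_cutoff)

    rec = next((r for r in backbone_dihedrals(model, residue.chain_id)
                if r.rid == residue.rid), None)
    phi = rec.phi if rec else None
    psi = rec.psi if rec else None
    rama = procheck_region(phi, psi, residue.res_name)
    return StrainReport(
        residue=residue,
        z_scores=z_scores,
        outlier_flags=flags,
        z_threshold=z_threshold,
        delta_omega=angle_set.delta_omega,
        cb_contacts=contacts,
        cb_strained=strained,
        rama_class=rama,
        in_forbidden_quadrant=forbidden_quadrant(phi, psi),
        phi=phi,
        psi=psi,
    )
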