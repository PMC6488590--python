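"""Synthetic stand-ins for the arginine-binding-protein motif region.

These are *synthetic* models — idealized-geometry constructions, not
deposited coordinates. They emulate the helix-insertion motif of the
thermophilic arginine binding protein's D1 domain with author numbering
36-60: an N-terminal helix turn (residues 36-41, with Pro40 and Phe41
providing the locking carbonyls), a 10-residue inserted hairpin (42-51
ending in Val51), the C0 residue 52 pinned at the ε-region conformation
(φ, ψ) = (117.3°, −170.9°) reported for the Gly52Ala mutant, and the
continuing helix 53-60 (Phe53 and Asp54 donating the locking amides,
Asp56 donating the helical H-bond back to the C0 carbonyl).

The backbone dihedrals ship as a frozen package resource: the insertion
region was fitted once (scripts/dev/make_standin_dihedrals.py) so that the
two consecutive locking H-bonds (53→40, 54→41) and the C0 helical H-bond
(56→52) form, every non-C0 residue stays in an allowed Ramachandran
region, and no non-bonded atom approaches the residue-52 Cβ within the
3.4 Å clash radius.
"""

from __future__ import annotations

from importlib import resources

from ramastrain.structures import StructureModel
from ramastrain.synthetic import GeometryTable, build_peptide

__all__ = ["g52a_standin", "parent_standin", "STANDIN_SEQUENCE"]

#: One-letter sequence of the stand-in segment (positions 36-60). Only the
#: residues the motif analysis names (Pro40, Phe41, Val51, position 52,
#: Phe53, Asp54, Asp56) carry their real identities; the rest are alanines.
STANDIN_SEQUENCE = "AAAAPFAAAAAAAAAVXFDADAAAA"

START_NUMBER = 36
C0_POSITION = 52


def _load_dihedrals() -> list[tuple[float | None, float | None]]:
    text = resources.files("ramastrain").joinpath(
        "data/standin_dihedrals.csv").read_text()
    plan: list[tuple[float | None, float | None]] = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.startswith("seq_number"):
            continue
        _, phi, psi, _ = ln.split(",")
        plan.append((float(phi) if phi else None, float(psi) if psi else None))
    if len(plan) != len(STANDIN_SEQUENCE):
        raise ValueError("stand-in dihedral table does not match the sequence")
    return plan


def _build(res52_letter: str, structure_id: str,
           geometry: GeometryTable | None = None,
           resolution: float = 1.64) -> StructureModel:
    seq = STANDIN_SEQUENCE.replace("X", res52_letter)
    model = build_peptide(seq, _load_dihedrals(), geometry=geometry,
                          start_number=START_NUMBER, structure_id=structure_id)
    model.resolution = resolution
    return model


def g52a_standin(geometry: GeometryTable | None = None) -> StructureModel:
    """Synthetic stand-in for the Gly52Ala mutant: Ala at the C0 position,
    pinned at the ε conformation that is forbidden to Cβ-bearing residues."""
    return _build("A", "g52a-standin-synthetic", geometry)


def parent_standin(geometry: GeometryTable | None = None) -> StructureModel:
    """Synthetic stand-in for the parent protein: Gly at the C0 position,
    same backbone conformation (the ε region is allowed for Gly).

    The Gly is built with the shared (non-Gly) backbone bond geometry so
    that parent and mutant stand-ins have identical backbones — mirroring
    the experimental observation that the mutation leaves the structure
    essentially unchanged — and the motif H-bonds are bitwise the same.
    """
    if geometry is None:
        base = GeometryTable.default()
        geometry = GeometryTable({k: v for k, v in base._rows.items()
                                  if k[0] != "GLY"})
    return _build("G", "parent-standin-synthetic", geometry)
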