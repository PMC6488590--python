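"""Ramachandran region classification and (φ,ψ)-box census.

Three classifiers are provided:

* :func:`in_box` — membership in an arbitrary square (φ,ψ) box, periodic in
  both angles, used for the 10°×10° box census centred at (117°, −170°);
* :func:`forbidden_quadrant` — the lower-right quadrant strictly forbidden
  to residues carrying a Cβ (φ in 90…180, ψ in −180…−80), which contains
  the Gly-only ε region;
* :func:`procheck_region` — a packaged 10°-binned four-class map
  (most favored / additional / generous / disallowed) in the style of the
  classic Ramachandran quality classification.

:func:`census` runs the archive-style occupancy count: first models only,
resolution filter, Gly vs non-Gly partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from ramastrain.errors import RamastrainError
from ramastrain.geometry import backbone_dihedrals, wrap_angle
from ramastrain.structures import StructureModel, read_structure

__all__ = [
    "BoxSpec", "CensusResult", "in_box", "forbidden_quadrant",
    "procheck_region", "census", "REGION_LABELS",
]

logger = logging.getLogger(__name__)

REGION_LABELS = {
    "F": "most_favored",
    "A": "additional",
    "G": "generous",
    "D": "disallowed",
}


@dataclass(frozen=True)
class BoxSpec:
    """A square (φ,ψ) box; defaults to the 10°×10° census box centred at
    (117°, −170°)."""

    center_phi: float = 117.0
    center_psi: float = -170.0
    width: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.width <= 360.0:
            raise ValueError("box width must be in (0, 360]")


@dataclass
class CensusResult:
    """Counts of residues inside a (φ,ψ) box, split Gly vs non-Gly.

    Totals count every residue with defined (φ,ψ) in the structures that
    passed the resolution filter; the same residues are the denominator of
    the in-box fractions.
    """

    gly_in: int = 0
    gly_total: int = 0
    nongly_in: int = 0
    nongly_total: int = 0
    n_structures_used: int = 0
    n_structures_excluded: int = 0
    hits: list[dict] = field(default_factory=list)

    def __add__(self, other: "CensusResult") -> "CensusResult":
        return CensusResult(
            self.gly_in + other.gly_in,
            self.gly_total + other.gly_total,
            self.nongly_in + other.nongly_in,
            self.nongly_total + other.nongly_total,
            self.n_structures_used + other.n_structures_used,
            self.n_structures_excluded + other.n_structures_excluded,
            self.hits + other.hits,
        )

    def as_dict(self) -> dict:
        return {
            "gly_in": self.gly_in, "gly_total": self.gly_total,
            "nongly_in": self.nongly_in, "nongly_total": self.nongly_total,
            "n_structures_used": self.n_structures_used,
            "n_structures_excluded": self.n_structures_excluded,
        }


def in_box(phi: float | None, psi: float | None, box: BoxSpec = BoxSpec()) -> bool:
    """True iff (φ,ψ) falls in the box, periodic with period 360.

    Bounds are half-open: the periodic offset from each centre must lie in
    [−width/2, width/2), so disjoint box tilings partition the torus.
    Undefined dihedrals are never in any box.
    """
    if phi is None or psi is None:
        return False
    half = box.width / 2.0
    for angle, center in ((phi, box.center_phi), (psi, box.center_psi)):
        off = wrap_angle(angle - center)
        if off == 180.0:  # wrap_angle maps −180 to +180; reopen the interval
            off = -180.0
        if not (-half <= off < half):
            return False
    return True


def forbidden_quadrant(phi: float | None, psi: float | None) -> bool:
    """Membership in the quadrant forbidden to Cβ-bearing residues.

    True iff φ ∈ [90, 180] and ψ (with +180 treated as −180) ∈ [−180, −80].
    Both bounds inclusive. This quadrant contains the ε region where the Cβ
    clashes with O(i−1) and N(i+1).
    """
    if phi is None or psi is None:
        return False
    phi_w = wrap_angle(phi)
    psi_w = wrap_angle(psi)
    if psi_w == 180.0:
        psi_w = -180.0
    return 90.0 <= phi_w <= 180.0 and -180.0 <= psi_w <= -80.0


# ---------------------------------------------------------------------------
# packaged four-class grid

_GRID: list[str] | None = None


def _load_grid() -> list[str]:
    """36 rows of 36 class symbols; row 0 is ψ ∈ [170, 180), column 0 is
    φ ∈ [−180, −170)."""
    global _GRID
    if _GRID is None:
        text = resources.files("ramastrain").joinpath("data/rama_grid.csv").read_text()
        rows = [ln.strip() for ln in text.splitlines()
                if ln.strip() and not ln.startswith("#")]
        if len(rows) != 36 or any(len(r) != 36 for r in rows):
            raise RamastrainError("packaged Ramachandran grid is malformed")
        _GRID = rows
    return _GRID


def procheck_region(phi: float | None, psi: float | None,
                    res_class: str = "other") -> str:
    """Four-class Ramachandran label from the packaged 10°-binned grid.

    res_class is 'GLY', 'PRO' or 'other' (any standard residue name other
    than GLY/PRO is treated as 'other'). Gly and Pro are not scored against
    the main grid and return 'not_assessed', consistent with classifiers
    that count disallowed conformations over standard residues only.
    """
    if phi is None or psi is None:
        return "not_assessed"
    rc = res_class.upper()
    if rc in ("GLY", "PRO"):
        return "not_assessed"
    grid = _load_grid()
    phi_w = wrap_angle(phi)
    psi_w = wrap_angle(psi)
    col = int((phi_w + 180.0) // 10) % 36
    row = 35 - (int((psi_w + 180.0) // 10) % 36)
    return REGION_LABELS[grid[row][col]]


# ---------------------------------------------------------------------------
# census

def census(structures: Iterable[StructureModel | str | Path],
           box: BoxSpec = BoxSpec(),
           max_resolution: float = 2.0,
           keep_hits: bool = True) -> CensusResult:
    """Occupancy census of a (φ,ψ) box over a structure set.

    Iterates first models only; a structure enters the census when its
    header resolution is present and strictly better than (less than)
    max_resolution, else it is excluded. Every polymer residue with defined
    (φ,ψ) is counted, partitioned Gly vs non-Gly; unreadable members are
    logged, counted as excluded, and the census continues.
    """
    result = CensusResult()
    for item in structures:
        if isinstance(item, (str, Path)):
            try:
                model = read_structure(item)[0]
            except (RamastrainError, OSError) as exc:
                logger.warning("census: skipping unreadable %s (%s)", item, exc)
                result.n_structures_excluded += 1
                continue
        else:
            model = item
        if model.resolution is None or model.resolution >= max_resolution:
            result.n_structures_excluded += 1
            continue
        result.n_structures_used += 1
        for rec in backbone_dihedrals(model):
            if rec.phi is None or rec.psi is None:
                continue
            is_gly = rec.residue.res_name == "GLY"
            hit = in_box(rec.phi, rec.psi, box)
            if is_gly:
                result.gly_total += 1
                result.gly_in += int(hit)
            else:
                result.nongly_total += 1
                result.nongly_in += int(hit)
            if hit and keep_hits:
                result.hits.append({
                    "structure": model.structure_id,
                    "chain": rec.residue.chain_id,
                    "resnum": rec.residue.seq_number,
                    "resname": rec.residue.res_name,
                    "phi": rec.phi, "psi": rec.psi,
                })
    return result
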