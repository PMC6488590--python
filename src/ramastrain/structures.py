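"""Atomic-structure and trajectory containers plus PDB/mmCIF I/O.

Parsing and writing of the crystallographic formats is delegated to gemmi;
this module normalises the result into light-weight containers shared by all
analysis code: alternate locations are resolved deterministically at read
time (highest occupancy wins, ties broken by the lexicographically smallest
altloc identifier), residue identity is the author numbering so that
reported residues match published descriptions, and the header resolution is
exposed as a single number for downstream resolution filtering.

Hydrogens, waters and hetero-residues (ligands) are retained in the model —
they must stay visible to clash scans — but are excluded from backbone
analyses via :meth:`StructureModel.polymer_residues`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from ramastrain.errors import EmptyModelError, FormatError, StructureError

__all__ = [
    "AtomRecord", "ResidueRecord", "StructureModel", "Trajectory",
    "read_structure", "write_structure", "read_trajectory", "write_trajectory",
]

#: Standard 20 amino acids, used to separate polymer from hetero residues
#: when a file provides no entity information.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class AtomRecord:
    """One atom after altloc resolution.

    coords are Cartesian, in Å; b_factor is the isotropic displacement
    parameter in Å²; altloc records the chosen alternate-location label
    (empty string when the atom had a single location).
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise StructureError(f"atom {self.name}: negative B-factor")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueRecord:
    """A residue identified by (chain, author seq number, insertion code)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    het: bool = False

    def __post_init__(self) -> None:
        self.res_name = self.res_name.upper()

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def rid(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_number}{self.insertion_code}"

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    @property
    def is_water(self) -> bool:
        return self.res_name in ("HOH", "DOD", "WAT")


@dataclass
class StructureModel:
    """A single model: ordered chains of residues plus header metadata.

    resolution is the header (refinement) high-resolution limit in Å, or
    None when the file declares none; census-style resolution filters treat
    absent resolution as excluded.
    """

    structure_id: str
    model_number: int = 1
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    resolution: float | None = None
    experiment_type: str = ""

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise StructureError("resolution must be positive when present")

    def residues(self) -> Iterator[ResidueRecord]:
        """All residues in file order, hetero and waters included."""
        for chain in self.chains.values():
            yield from chain

    def polymer_residues(self, chain_id: str | None = None) -> list[ResidueRecord]:
        """Amino-acid residues of one chain (or all), in order.

        Hetero-residues and waters are skipped; this is the iteration basis
        for every backbone analysis.
        """
        out = []
        for cid, chain in self.chains.items():
            if chain_id is not None and cid != chain_id:
                continue
            out.extend(r for r in chain if not r.het and not r.is_water
                       and r.res_name in AMINO_ACIDS)
        return out

    def find_residue(self, chain_id: str, seq_number: int,
                     insertion_code: str = "") -> ResidueRecord | None:
        for r in self.chains.get(chain_id, []):
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def all_coords(self) -> np.ndarray:
        """(n_atoms, 3) array over all atoms in file order."""
        n = self.atom_count()
        out = np.empty((n, 3))
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            out[i] = a.coords
        return out

    def iter_atoms(self) -> Iterator[tuple[ResidueRecord, int, AtomRecord]]:
        for r in self.residues():
            for i, a in enumerate(r.atoms):
                yield r, i, a


@dataclass
class Trajectory:
    """Frames congruent with a topology model.

    coords has shape (n_frames, n_atoms, 3) with atoms in the topology's
    file order; time_step is ns per frame when known.
    """

    topology: StructureModel
    coords: np.ndarray
    time_step: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.atom_count():
            raise StructureError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.atom_count()}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_model(self, i: int) -> StructureModel:
        """Materialise frame i as a StructureModel (same topology, frame coords)."""
        model = _copy_topology(self.topology)
        k = 0
        for r in model.residues():
            for a in r.atoms:
                a.coords = self.coords[i, k].copy()
                k += 1
        model.model_number = i + 1
        return model

    def atom_indices(self, predicate) -> np.ndarray:
        """Flat atom indices for which predicate(residue, atom) is true."""
        idx = [i for i, (r, _, a) in enumerate(self.topology.iter_atoms())
               if predicate(r, a)]
        return np.asarray(idx, dtype=int)

    def ca_indices(self) -> np.ndarray:
        return self.atom_indices(
            lambda r, a: a.name == "CA" and not r.het and not r.is_water)


def _copy_topology(model: StructureModel) -> StructureModel:
    chains: dict[str, list[ResidueRecord]] = {}
    for cid, chain in model.chains.items():
        chains[cid] = [
            ResidueRecord(r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                          [AtomRecord(a.name, a.element, a.coords.copy(),
                                      a.occupancy, a.b_factor, a.altloc)
                           for a in r.atoms],
                          het=r.het)
            for r in chain
        ]
    return StructureModel(model.structure_id, model.model_number, chains,
                          model.resolution, model.experiment_type)


# ---------------------------------------------------------------------------
# reading

def _cif_resolution(path: str | Path) -> float | None:
    """High-resolution limit from an mmCIF file (None for non-CIF input)."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except (RuntimeError, ValueError):
        return None
    for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
        raw = block.find_value(tag)
        if raw not in (None, ".", "?"):
            try:
                val = float(raw.split("(")[0])
            except ValueError:
                continue
            if val > 0:
                return val
    return None


def _choose_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties broken by smallest altloc label."""
    def key(a: gemmi.Atom):
        alt = a.altloc if a.altloc and a.altloc != "\x00" else ""
        return (-a.occ, alt)
    return sorted(atoms, key=key)[0]


def _convert_model(st: gemmi.Structure, gmodel: gemmi.Model,
                   model_number: int) -> StructureModel:
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in gmodel:
        residues: list[ResidueRecord] = []
        for res in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                groups.setdefault(atom.name, []).append(atom)
            atoms = []
            for name in groups:
                chosen = _choose_altloc(groups[name])
                alt = chosen.altloc if chosen.altloc and chosen.altloc != "\x00" else ""
                atoms.append(AtomRecord(
                    name=name,
                    element=chosen.element.name,
                    coords=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                    occupancy=float(min(max(chosen.occ, 0.0), 1.0)),
                    b_factor=float(max(chosen.b_iso, 0.0)),
                    altloc=alt,
                ))
            het = res.het_flag == "H" and res.name not in AMINO_ACIDS
            residues.append(ResidueRecord(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name,
                atoms=atoms,
                het=het,
            ))
        if residues:
            chains[chain.name] = residues
    name = st.name or "model"
    return StructureModel(
        structure_id=name,
        model_number=model_number,
        chains=chains,
        resolution=resolution,
        experiment_type=str(st.info["_exptl.method"] if "_exptl.method" in st.info else ""),
    )


def read_structure(path: str | Path, format: str | None = None) -> list[StructureModel]:
    """Read a PDB or mmCIF file into one StructureModel per model.

    format may be 'pdb' or 'mmcif'; when None it is detected from the file.
    Alternate locations are resolved at read time (see module docstring) and
    the header resolution, when declared, is attached to every model.
    """
    path = Path(path)
    fmt = {None: gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format, None)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use 'pdb' or 'mmcif'")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {format or 'structure'}: {exc}") from exc
    st.setup_entities()
    if not st.resolution or st.resolution <= 0:
        # minimal mmCIF files: take the refinement high-resolution limit,
        # else the reflections resolution field
        res = _cif_resolution(path)
        if res is not None:
            st.resolution = res
    models = [_convert_model(st, m, i + 1) for i, m in enumerate(st)]
    models = [m for m in models if m.atom_count() > 0]
    if not models:
        raise EmptyModelError(f"{path} contains no atoms")
    return models


def _to_gemmi(models: Sequence[StructureModel]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = models[0].structure_id
    if models[0].resolution is not None:
        st.resolution = models[0].resolution
    for i, model in enumerate(models):
        gm = gemmi.Model(i + 1)
        for cid, chain in model.chains.items():
            gc = gemmi.Chain(cid)
            for r in chain:
                gr = gemmi.Residue()
                gr.name = r.res_name
                gr.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
                gr.het_flag = "H" if (r.het or r.is_water) else "A"
                for a in r.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_factor
                    if a.altloc:
                        ga.altloc = a.altloc
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel | Sequence[StructureModel],
                    path: str | Path, format: str = "pdb") -> None:
    """Write one model (or a model list, as a multi-model file) as PDB.

    Output re-reads with coordinates equal to 1e-3 Å, the fixed-column
    precision of the format.
    """
    models = [model] if isinstance(model, StructureModel) else list(model)
    if not models or all(m.atom_count() == 0 for m in models):
        raise EmptyModelError("refusing to write an empty model")
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    st = _to_gemmi(models)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# trajectories

def read_trajectory(path: str | Path, time_step: float | None = None) -> Trajectory:
    """Read a multi-model coordinate file as a trajectory.

    Models become frames in file order; every model must contain the same
    atoms in the same order, otherwise a StructureError is raised.
    """
    models = read_structure(path)
    topo = models[0]
    n_atoms = topo.atom_count()
    names0 = [(r.rid, a.name) for r, _, a in topo.iter_atoms()]
    coords = np.empty((len(models), n_atoms, 3))
    for f, m in enumerate(models):
        names = [(r.rid, a.name) for r, _, a in m.iter_atoms()]
        if names != names0:
            raise StructureError(
                f"frame {f + 1} of {path} has a different atom inventory "
                f"({len(names)} atoms vs {n_atoms})")
        coords[f] = m.all_coords()
    return Trajectory(topology=topo, coords=coords, time_step=time_step)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    frames = [traj.frame_model(i) for i in range(traj.n_frames)]
    write_structure(frames, path)


def chain_break(prev: ResidueRecord, curr: ResidueRecord,
                max_peptide_bond: float = 2.5) -> bool:
    """True when the peptide bond C(prev)–N(curr) is missing or > 2.5 Å."""
    c = prev.coord("C")
    n = curr.coord("N")
    if c is None or n is None:
        return True
    return bool(math.dist(c, n) > max_peptide_bond)
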