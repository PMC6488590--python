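# ramastrain

Backbone-strain and Ramachandran analysis of residues trapped in
"forbidden" conformations, with the thermodynamic side of the story: a
toolkit for structural biologists studying how a protein's context can
force a non-glycine residue into a backbone conformation that steric
theory disallows, and what that strain costs in stability.

The motivating system is a helix-insertion motif — a segment inserted
within an α-helix and locked by two consecutive backbone C=O···H-N
hydrogen bonds between the flanking helix residues. The residue just
before the first locking donor (the **C0 position**) is normally a glycine
sitting in the ε region of the Ramachandran plot (φ ≈ 90…180°,
ψ ≈ −180…−80°), a region forbidden to Cβ-bearing residues because the Cβ
clashes with the preceding carbonyl oxygen O(i−1) and the following amide
nitrogen N(i+1). Mutating that glycine to alanine leaves the structure
almost unchanged but destabilizes the protein by roughly 8–12 °C in
melting temperature and ~350 kJ/mol in denaturation enthalpy — strain you
can measure.

## What the package computes

* **Backbone geometry** — torsions φ, ψ, ω (IUPAC sign convention,
  cis = 0), peptide-planarity deviation Δω, the monitored valence angles
  (NCαC, NCαCβ, CβCαC, CαC O, CαC N₊₁, OC N₊₁, C₋₁NCα) with z-scores
  against an Engh–Huber-style reference, Cβ strain-contact distances, and
  Kabsch least-squares Cα superposition (proper rotations only).
* **Ramachandran census** — classification of (φ, ψ) into a packaged
  10°-binned four-class map (most favored / additional / generous /
  disallowed), the non-Gly forbidden quadrant, arbitrary periodic
  (φ, ψ) boxes, and an archive-style census engine with Gly/non-Gly
  partition and a resolution-better-than-2.0-Å filter.
* **Motif detection** — geometric backbone H-bonds
  (N···O ≤ 3.5 Å, C=O···N ≥ 120°) and helix-insertion motifs: locking
  pairs (j→i, j+1→i+1 with j − i ≥ 6), insertion range, C0 position, and
  the C0→C0+4 helical H-bond.
* **Trajectory statistics** — per-residue (φ, ψ) series and region
  occupancy over an equilibration window, RMSD/Rg series, RMSF-derived
  pseudo B-factors (B = 8π²/3 · MSF) with Carugo-style standardization,
  and RMSIP convergence between two windows over the first 10 covariance
  eigenvectors of the Cα motion.
* **Thermal stability** — two-state N ↔ D analysis with
  K(T) = exp[−(ΔH/R)(1/T − 1/T_d)]: nonlinear fits of CD melting curves
  with linear baselines, and model-free DSC analysis (T_d = peak maximum,
  ΔdH = peak area, ΔvH = 4RT_d²·Cp_max/ΔdH, cooperative unit
  CU = ΔdH/ΔvH).
* **Synthetic data** — every input class with exact ground truth: an
  internal-to-Cartesian peptide builder (dihedrals exact to 1e-6°),
  planted census sets, trajectories with prescribed occupancy and
  fluctuation profiles, and two-state melting/DSC curves.

Deposited crystal structures are not bundled; the package ships
*synthetic stand-ins* (`ramastrain.standins`) that rebuild the motif
topology and the published C0 conformation (φ, ψ) = (117.3°, −170.9°)
from idealized geometry, so the whole pipeline runs offline.

## Worked example

```python
from ramastrain import (backbone_dihedrals, cb_contact_distances,
                        find_hbonds, find_helix_insertions, procheck_region)
from ramastrain.standins import g52a_standin

model = g52a_standin()                     # synthetic Gly→Ala stand-in
rec = next(r for r in backbone_dihedrals(model)
           if r.residue.seq_number == 52)
print(f"C0 residue 52: phi={rec.phi:.1f}, psi={rec.psi:.1f}, "
      f"class={procheck_region(rec.phi, rec.psi, 'ALA')}")
res52 = model.find_residue("A", 52)
d_prev, d_next = cb_contact_distances(model, res52)
print(f"Cb-O(51)={d_prev:.2f} A, Cb-N(53)={d_next:.2f} A")
hit = find_helix_insertions(model, find_hbonds(model))[0]
print(f"motif: acceptors {hit.acceptors}, donors {hit.donors}, "
      f"C0={hit.c0[1]}, insertion={hit.insertion_length} residues")
```

prints

```
C0 residue 52: phi=117.3, psi=-170.9, class=disallowed
Cb-O(51)=2.32 A, Cb-N(53)=2.86 A
motif: acceptors (40, 41), donors (53, 54), C0=52, insertion=10 residues
```

The alanine at C0 measures exactly the ε-region conformation it was built
at and is classified disallowed; with ideal covalent geometry its Cβ sits
2.3 Å from the preceding carbonyl oxygen and 2.9 Å from the following
amide nitrogen — both far inside van der Waals contact, which is why the
region is forbidden to Cβ-bearing residues in the first place (refined
crystal structures relieve the O-side clash to ~2.8 Å through valence-angle
deformation). The motif detector recovers the two locking H-bonds
(53→40, 54→41), the 10-residue insertion, and the C0 position.

The same analyses are available from the shell, e.g.

```
ramastrain thermo-fit dsc.csv --mode dsc
```

on a simulated two-state thermogram (T_d 105.3 °C, ΔH 1000 kJ/mol) prints

```
Two-state thermal analysis
------------------------------
mode               dsc
Td (degC)          105.20
dH_cal (kJ/mol)    1000.0
dH_vH (kJ/mol)     998.2
CU = dH_cal/dH_vH  1.00
```

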