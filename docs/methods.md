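# Methods

This note documents the models, conventions and design choices behind
`ramastrain`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Backbone geometry

Torsions follow the IUPAC/Klyne–Prelog convention: the eclipsed (cis)
arrangement is 0°, the sign is right-handed about the central bond, and
all angles are reported in degrees in the half-open range (−180, 180]
with an exact −180 mapped to +180. A consequence worth stating because it
is often mis-remembered: the torsion is *invariant* under chain reversal
(the angle of D–C–B–A equals that of A–B–C–D, sign included); the test
suite asserts this identity.

φ_i = C_{i−1}–N_i–CA_i–C_i, ψ_i = N_i–CA_i–C_i–N_{i+1},
ω_i = CA_{i−1}–C_{i−1}–N_i–CA_i. Chaining breaks — and the affected
dihedrals become undefined — when backbone atoms are missing or the
peptide C–N distance exceeds 2.5 Å, so gapped crystallographic models
never contribute spurious dihedrals to a census. Peptide planarity is
summarised as Δω, the signed deviation from the nearer planar ideal
(180° for trans when |ω| > 90°, 0° for cis), wrapped through ±180 so that
ω = −178° gives Δω = +2°.

Valence-angle strain is scored as z = (observed − mean)/σ against a
packaged Engh–Huber-style reference table (`data/engh_huber.csv`;
class-specific rows for Gly and Pro, fallback to the generic residue
class). The carbonyl angles are kept internally consistent
(CαCO + CαCN₊₁ + OCN₊₁ = 360°) so a planar carbonyl reproduces the table
exactly; the Pro row therefore only overrides the nitrogen-side angles.
The default outlier threshold is |z| ≥ 3 (conventional; configurable).
The reference is conformation-independent; a (φ,ψ)-dependent reference
can be supplied as a custom `GeometryTable`, but no such regression model
is shipped.

Cβ strain contacts are the distances Cβ(i)–O(i−1) and Cβ(i)–N(i+1),
flagged below 3.1 Å (C/O and C/N van der Waals contact minus a 0.2 Å
tolerance; configurable). The surrounding-contact scan reports all
non-hydrogen atoms within a radius of a probe atom, excluding the
residue's own atoms, atoms within three covalent bonds of the probe (the
standard 1-4 clash-scan exclusion; for a Cβ probe this removes the
preceding carbonyl carbon) and the two strain partners above. Waters and
ligands stay visible to the scan.

Superposition is the Kabsch least-squares algorithm restricted to proper
rotations (the mirror determinant is folded into the smallest singular
vector), cross-checked in the tests against an independent library
implementation. Structure-to-structure RMSD pairs residues by
(chain, author number); no sequence alignment is attempted.

## Ramachandran classification and census

Three region notions are used.

* An arbitrary square box, periodic in both angles with period 360° and
  half-open bounds [c − w/2, c + w/2), so that disjoint box tilings
  partition the torus. The default is the 10°×10° box centred at
  (117°, −170°).
* The quadrant forbidden to Cβ-bearing residues: φ ∈ [90, 180] and
  ψ ∈ [−180, −80] (ψ = +180 ≡ −180), bounds inclusive. This contains the
  Gly-only ε region.
* A packaged 36×36 (10°-binned) four-class map in the style of the
  classic crystallographic validation classification. The shipped grid is
  a *reconstruction* generated from polygonal region definitions
  (core β, α and left-handed basins; additional regions including the
  β wrap through ψ = ±180; a 20° dilation for the generous class) by
  `scripts/dev/make_rama_grid.py`, not a copy of any program's data file.
  Gly and Pro are not scored against the main grid and return
  `not_assessed`, so "disallowed" counts refer to standard residues only.

The census engine iterates first models only, applies a strictly-better-
than resolution filter (default 2.0 Å; structures with no declared
resolution are excluded), counts every polymer residue with defined
(φ, ψ) partitioned Gly vs non-Gly, counts all chains (including
sequence-identical copies), and is additive over disjoint structure sets.
Archive-scale censuses additionally depend on the snapshot of the archive
used; the engine is validated on planted synthetic sets where ground
truth is exact.

## Hydrogen bonds and the helix-insertion motif

X-ray models usually lack hydrogens, so H-bonds use the heavy-atom
geometric proxy: donor amide N to acceptor carbonyl O with
N···O ≤ 3.5 Å and C=O···N angle ≥ 120°, sequence separation ≥ 2 within a
chain, prolines never donating. A helix-insertion motif is reported for
every pair of H-bonds (j→i) and (j+1→i+1) with j − i ≥ 6: the insertion
is i+2 … j−2 (length j − i − 3 ≥ 3, which excludes canonical α-helical
i→i+4 bonds and tight turns), C0 = j − 1, and the C0→C0+4 helical H-bond
is reported as a flag. Removing either locking bond removes the hit.

## Synthetic data

The peptide builder places each atom from one bond length, one valence
angle and one torsion (natural-extension-of-reference-frame chaining), so
measured dihedrals equal the request to 1e-6° and measured valence angles
equal the reference table exactly — the end-to-end oracle used throughout
the tests. Cβ is placed by solving both Cβ angles with L-chirality;
ω defaults to 180° (trans). Per-residue angle overrides build strained
fixtures with exactly known z-scores.

The motif stand-ins (`ramastrain.standins`) rebuild the helix-insertion
topology with author numbering 36–60: helix 36–41, a fitted 10-residue
insertion 42–51, the C0 residue 52 pinned at (117.3°, −170.9°), helix
53–60. The free insertion dihedrals were optimised once (least squares on
the builder, bounded inside allowed Ramachandran regions) so that the
locking H-bonds 53→40 and 54→41 and the helical bond 56→52 form, no atom
approaches the C0 Cβ within the clash radius, and no other atom pair
clashes; the converged dihedrals ship as a frozen CSV. The parent
stand-in places Gly at C0 using the shared backbone geometry so parent
and mutant have bitwise-identical backbones — an idealisation of the
experimental finding that the mutation barely perturbs the structure.
Only the residues the motif analysis names (Pro40, Phe41, Val51,
position 52, Phe53, Asp54, Asp56) carry their real identities; the rest
are alanines, and only backbone + Cβ atoms exist. What stand-in tests
demonstrate is therefore that the *algorithms* recover planted/derived
ground truth and that the C0 conformation itself implies the strain
contacts; they do not validate against deposited coordinates, and
coordinate-level quantities of real structure pairs (e.g. a 0.29 Å
Cα RMSD between two refined models) are outside what synthetic data can
reproduce. With ideal geometry the O-side Cβ contact comes out at 2.32 Å,
*tighter* than the ~2.8 Å seen in refined models, because real structures
relieve the clash through valence-angle deformation (most prominently
NCαCβ) that idealized construction deliberately omits.

Planted census sets scatter exact numbers of Gly/non-Gly residues at a
chosen (φ, ψ) over α-helical poly-alanine chains with declared
resolutions. Synthetic trajectories draw the target residue's (φ, ψ)
per frame from a categorical mixture of region samplers (binomial
occupancy by construction) and add independent Gaussian atom
displacements with per-residue σ. Two-state thermal curves use
K(T) = exp[−(ΔH/R)(1/T − 1/T_d)] (T in kelvin, R = 8.314 J mol⁻¹ K⁻¹):
the melt signal is the population-weighted average of two linear
baselines; the DSC excess heat capacity is ΔH²K/(RT²(1+K)²) plus a
linear native baseline. All generators are seed-deterministic. None of
the generators emulate instrument drift, irreversible aggregation,
scan-rate effects, force-field bias or crystallographic disorder — tests
passing on them validate the estimators, not those phenomena.

## Trajectory statistics

Region occupancy is the fraction of window frames whose (φ, ψ) satisfies
a predicate. Pseudo B-factors are B = (8π²/3)·MSF per Cα after
superposing every window frame onto the window-average structure (one
refinement iteration); superposition absorbs rigid-body motion and, with
it, 6 of the 3N fluctuation degrees of freedom — for isotropic noise the
recovered B underestimates 8π²σ² by ≈ 6/(3N), which is why analytic
comparisons in the tests use chains long enough to make that bias small
against the stated tolerance. Standardization is z = (B − mean)/SD with
the *population* SD (fixed convention), making profiles affine-invariant
and cross-model comparable. RMSIP between two windows eigen-decomposes
each window's Cα covariance (after superposition, via SVD of the centred
coordinate matrix) and reports
sqrt((1/n)·Σ_ab (η_a·ν_b)²) over the first n = 10 modes by default;
identical windows give 1, orthogonal fluctuation subspaces give 0.
Windows are specified in frames; a time step in ns/frame is metadata the
caller may attach (the CLI converts).

## Thermal analysis

CD melts are fitted by bounded nonlinear least squares to
signal(T) = [θ_N(T) + θ_D(T)K(T)]/(1+K(T)) with linear native/denatured
baselines; T_d is the fitted midpoint (K = 1), with the derivative-
extremum temperature reported as a cross-check. A curve that a straight
line explains to within the noise raises a no-transition error rather
than returning a meaningless fit. DSC thermograms are analysed
model-free: the native baseline is fitted linearly on the coolest 20% of
the temperature range (configurable) and subtracted, T_d is the
excess-Cp maximum (reported at grid resolution, no interpolation),
ΔdH is the trapezoidal peak area, ΔvH = 4RT_d²·Cp_max/ΔdH, and
CU = ΔdH/ΔvH. For an exact two-state peak CU = 1; summing two separated
transitions and analysing the composite as one peak inflates CU above 1
(full area, single-component height). At finite noise the dominant ΔdH
uncertainty is the extrapolation of the fitted baseline under the peak,
not the integrated noise itself; the consistency tests use per-noise
tolerances accordingly. Temperatures are °C at every interface and kelvin
inside every formula; enthalpies are kJ/mol.

## Problem sizes and determinism

The shipped validation workloads are sized for interactive runs: planted
census sets of 50 structures × 200 residues (~10⁴ dihedrals), occupancy
and fluctuation trajectories of 2000 frames on 9–60-residue helices, and
thermal grids of 400–850 points. Every stochastic step takes an explicit
seed; `scripts/acceptance.py --seed N` threads one seed through all of
them and writes every measured quantity to JSON.

## Known limitations

* PDB and mmCIF input, multi-model PDB trajectories only; no binary MD
  formats, no symmetry expansion, no assemblies.
* One altloc per atom survives reading (highest occupancy, ties to the
  lexicographically smallest label); mixed-occupancy ensembles are not
  propagated.
* The four-class grid is a documented reconstruction; counts near region
  boundaries can differ from any specific validation-program release.
* The geometry reference is conformation-independent; genuinely
  conformation-dependent expectations require a user-supplied table.
* No side-chain χ angles, rotamer analysis, hydrogen placement or
  energy-based H-bond scoring.
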