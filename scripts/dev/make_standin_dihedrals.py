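"""Fit and freeze the dihedrals of the synthetic helix-insertion stand-in.

The stand-in emulates the helix-insertion motif of the arginine binding
protein's D1 domain (residues 36-60 by author numbering): an N-terminal
helix turn (36-41), a 10-residue inserted hairpin (42-51), the C0 residue
52 pinned at the epsilon conformation (117.3, -170.9), and the continuing
helix (53-60). The free (phi, psi) of the insertion and of the first
post-C0 helix turn are optimised so that

* the two consecutive locking H-bonds form: donor 53 N -> acceptor 40 O
  and donor 54 N -> acceptor 41 O,
* the C0 carbonyl accepts the helical H-bond from residue 56,
* no non-bonded atom approaches the residue-52 CB within 3.6 A,
* no other atom pair clashes,

with the free dihedrals bounded inside allowed Ramachandran regions. The
converged dihedrals are frozen into src/ramastrain/data/standin_dihedrals.csv
(consumed by ramastrain.standins) so tests and the acceptance script are
fast and deterministic. Run from the repository root:

    python scripts/dev/make_standin_dihedrals.py
"""

import sys
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

sys.path.insert(0, str(Path(__file__).resolve().parents[2] / "src"))

from ramastrain.geometry import bond_angle  # noqa: E402
from ramastrain.synthetic import build_peptide  # noqa: E402

START = 36
SEQ_MUT = "AAAAPFAAAAAAAAAVAFDADAAAA"  # 36..60, Ala52
EPS = (117.3, -170.9)
HELIX = (-57.0, -47.0)
STRAND = (-120.0, 130.0)
TURN = (55.0, 40.0)

# (seq number, initial (phi, psi), (phi_lo, phi_hi, psi_lo, psi_hi)) for the
# free residues; bounds keep every free residue inside allowed regions.
STRAND_B = (-165.0, -60.0, 80.0, 180.0)
TURN_B = (30.0, 80.0, 10.0, 80.0)
HELIX_B = (-90.0, -35.0, -70.0, -20.0)
FREE = (
    [(n, STRAND, STRAND_B) for n in (42, 43, 44, 45)]
    + [(46, TURN, TURN_B), (47, TURN, TURN_B)]
    + [(n, STRAND, STRAND_B) for n in (48, 49, 50, 51)]
    + [(n, HELIX, HELIX_B) for n in (53, 54, 55)]
)


def dihedral_plan(x):
    """Full (phi, psi) list for residues 36..60 given the free vector."""
    plan = {}
    for n in range(36, 61):
        plan[n] = HELIX
    plan[52] = EPS
    for k, (n, _, _) in enumerate(FREE):
        plan[n] = (x[2 * k], x[2 * k + 1])
    return [(None if n == START else plan[n][0],
             None if n == 60 else plan[n][1]) for n in range(36, 61)]


def build(x):
    return build_peptide(SEQ_MUT, dihedral_plan(x), start_number=START,
                         structure_id="standin-fit")


def hbond_terms(model):
    res = {r.seq_number: r for r in model.polymer_residues()}
    terms = []
    for acc, don in ((40, 53), (41, 54), (52, 56)):
        o, c = res[acc].coord("O"), res[acc].coord("C")
        n = res[don].coord("N")
        d = np.linalg.norm(n - o)
        ang = bond_angle(c, o, n)
        terms.append((d - 2.95) / 0.03)
        terms.append(max(0.0, 140.0 - ang) / 2.0)
    return terms


def clash_terms(model):
    residues = model.polymer_residues()
    coords, rid = [], []
    for i, r in enumerate(residues):
        for a in r.atoms:
            coords.append(a.coords)
            rid.append(i)
    coords = np.asarray(coords)
    rid = np.asarray(rid)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    sep = np.abs(rid[:, None] - rid[None, :])
    iu = np.triu_indices(len(coords), 1)
    mask = sep[iu] >= 2  # non-neighbouring residues only
    viol = np.maximum(0.0, 3.0 - d[iu][mask])
    # CB52 environment: nothing within 3.6 A except O51/C51 and N53
    cb = next(r for r in residues if r.seq_number == 52).coord("CB")
    near = []
    for r in residues:
        for a in r.atoms:
            if r.seq_number == 52:
                continue
            if (r.seq_number, a.name) in ((51, "O"), (51, "C"), (53, "N")):
                continue
            dd = np.linalg.norm(a.coords - cb)
            near.append(max(0.0, 3.6 - dd) / 0.05)
    return list(viol / 0.1) + near


def residuals_stage1(x):
    model = build(x)
    x0 = np.array([v for _, init, _ in FREE for v in init])
    return np.array(hbond_terms(model) + list((x - x0) / 200.0), dtype=float)


def residuals(x):
    model = build(x)
    x0 = np.array([v for _, init, _ in FREE for v in init])
    restraint = (x - x0) / 100.0
    return np.array(hbond_terms(model) + clash_terms(model)
                    + list(restraint), dtype=float)


def score(x):
    model = build(x)
    return float(np.sum(np.square(hbond_terms(model) + clash_terms(model))))


def main():
    x_init = np.array([v for _, init, _ in FREE for v in init])
    lo = np.array([b for _, _, bb in FREE for b in (bb[0], bb[2])])
    hi = np.array([b for _, _, bb in FREE for b in (bb[1], bb[3])])
    rng = np.random.default_rng(7)
    best, best_score = None, np.inf
    for trial in range(6):
        x0 = x_init if trial == 0 else np.clip(
            x_init + rng.uniform(-25, 25, size=x_init.shape), lo, hi)
        s1 = least_squares(residuals_stage1, x0, bounds=(lo, hi),
                           diff_step=1e-3, xtol=1e-12, ftol=1e-12,
                           max_nfev=3000)
        s2 = least_squares(residuals, s1.x, bounds=(lo, hi), diff_step=1e-3,
                           xtol=1e-12, ftol=1e-12, max_nfev=3000)
        sc = score(s2.x)
        print(f"trial {trial}: stage1 cost {s1.cost:.1f} -> final score {sc:.2f}")
        if sc < best_score:
            best, best_score = s2.x, sc
    sol_x = best
    model = build(sol_x)
    print("hbond residuals:", np.round(hbond_terms(model), 3))
    res = {r.seq_number: r for r in model.polymer_residues()}
    for acc, don in ((40, 53), (41, 54), (52, 56)):
        d = np.linalg.norm(res[don].coord("N") - res[acc].coord("O"))
        ang = bond_angle(res[acc].coord("C"), res[acc].coord("O"),
                         res[don].coord("N"))
        print(f"O{acc}..N{don}: {d:.3f} A, angle {ang:.1f}")
    plan = dihedral_plan(sol_x)
    out = (Path(__file__).resolve().parents[2]
           / "src/ramastrain/data/standin_dihedrals.csv")
    lines = [
        "# Frozen backbone dihedrals of the synthetic helix-insertion",
        "# stand-in (author numbering 36-60; residue 52 pinned at the",
        "# epsilon conformation). Regenerated by",
        "# scripts/dev/make_standin_dihedrals.py.",
        "seq_number,phi,psi,omega",
    ]
    for k, n in enumerate(range(36, 61)):
        phi = "" if plan[k][0] is None else f"{plan[k][0]:.4f}"
        psi = "" if plan[k][1] is None else f"{plan[k][1]:.4f}"
        lines.append(f"{n},{phi},{psi},180.0")
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
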