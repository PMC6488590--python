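"""Regenerate the packaged four-class Ramachandran grid.

The grid is a reconstruction of the classic 10°-binned four-class
classification map (core / additional / generous / disallowed) from simple
polygonal region definitions: rectangular core and additional regions for
the β, α-helical and left-handed-helical basins (the additional β region
wraps through ψ = ±180), with the generous class obtained by dilating the
allowed set by 20° (2 cells, Chebyshev, periodic) — the construction used
by the classic classification. Run from the repository root:

    python scripts/dev/make_rama_grid.py
"""

from pathlib import Path

CORE = [  # (phi_lo, phi_hi, psi_lo, psi_hi), cell centres inclusive
    (-170, -50, 100, 180),   # β / extended
    (-140, -40, -70, -10),   # right-handed α
    (40, 70, 20, 70),        # left-handed helical
]
ADDITIONAL = [
    (-180, -40, 50, 180),    # β expanded
    (-180, -40, -180, -160), # β wrap through ψ = ±180
    (-160, -20, -90, 60),    # α expanded + α/β bridge
    (20, 90, 0, 90),         # left-handed expanded
]
DILATE_CELLS = 2  # 20° generous margin


def centre(idx: int) -> float:
    return -180 + 10 * idx + 5


def in_rects(phi_c: float, psi_c: float, rects) -> bool:
    return any(plo <= phi_c <= phi_hi and slo <= psi_c <= shi
               for plo, phi_hi, slo, shi in rects)


def main() -> None:
    grid = [["D"] * 36 for _ in range(36)]  # [row=psi desc][col=phi asc]
    for r in range(36):
        psi_c = centre(35 - r)
        for c in range(36):
            phi_c = centre(c)
            if in_rects(phi_c, psi_c, CORE):
                grid[r][c] = "F"
            elif in_rects(phi_c, psi_c, ADDITIONAL):
                grid[r][c] = "A"
    allowed = {(r, c) for r in range(36) for c in range(36)
               if grid[r][c] in ("F", "A")}
    for r in range(36):
        for c in range(36):
            if grid[r][c] != "D":
                continue
            near = any(((r + dr) % 36, (c + dc) % 36) in allowed
                       for dr in range(-DILATE_CELLS, DILATE_CELLS + 1)
                       for dc in range(-DILATE_CELLS, DILATE_CELLS + 1))
            if near:
                grid[r][c] = "G"
    out = Path(__file__).resolve().parents[2] / "src/ramastrain/data/rama_grid.csv"
    lines = [
        "# Four-class Ramachandran grid, 10-degree bins.",
        "# Reconstruction of the classic core/additional/generous/disallowed",
        "# classification map from polygonal region definitions; regenerate",
        "# with scripts/dev/make_rama_grid.py.",
        "# Rows: psi 175 (top) to -175 (bottom); columns: phi -175 to 175.",
        "# F = most favored, A = additional, G = generous, D = disallowed.",
    ]
    lines += ["".join(row) for row in grid]
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
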