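# Four-class Ramachandran grid, 10-degree bins.
# Reconstruction of the classic core/additional/generous/disallowed
# classification map from polygonal region definitions; regenerate
# with scripts/dev/make_rama_grid.py.
# Rows: psi 175 (top) to -175 (bottom); columns: phi -175 to 175.
# F = most favored, A = additional, G = generous, D = disallowed.
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDDGG
AFFFFFFFFFFFFAGGDDGGGGGGGGGGGDDDDDGG
AAAAAAAAAAAAAAGGDDGGGGGGGGGGGDDDDDGG
AAAAAAAAAAAAAAGGDDGGAAAAAAAGGDDDDDGG
AAAAAAAAAAAAAAGGGGGGAAAAAAAGGDDDDDGG
AAAAAAAAAAAAAAGGGGGGAAFFFAAGGDDDDDGG
AAAAAAAAAAAAAAAAGGGGAAFFFAAGGDDDDDGG
GGAAAAAAAAAAAAAAGGGGAAFFFAAGGDDDDDGG
GGAAAAAAAAAAAAAAGGGGAAFFFAAGGDDDDDGG
GGAAAAAAAAAAAAAAGGGGAAFFFAAGGDDDDDDD
GGAAAAAAAAAAAAAAGGGGAAAAAAAGGDDDDDDD
GGAAAAAAAAAAAAAAGGGGAAAAAAAGGDDDDDDD
GGAAAAAAAAAAAAAAGGGGGGGGGGGGGDDDDDDD
GGAAFFFFFFFFFFAAGGGGGGGGGGGGGDDDDDDD
GGAAFFFFFFFFFFAAGGDDDDDDDDDDDDDDDDDD
GGAAFFFFFFFFFFAAGGDDDDDDDDDDDDDDDDDD
GGAAFFFFFFFFFFAAGGDDDDDDDDDDDDDDDDDD
GGAAFFFFFFFFFFAAGGDDDDDDDDDDDDDDDDDD
GGAAFFFFFFFFFFAAGGDDDDDDDDDDDDDDDDDD
GGAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDD
GGAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDD
GGGGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDD
GGGGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
GGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDDGG
GGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDDGG
AAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDDGG
AAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDDGG
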