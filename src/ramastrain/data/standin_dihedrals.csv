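# Frozen backbone dihedrals of the synthetic helix-insertion
# stand-in (author numbering 36-60; residue 52 pinned at the
# epsilon conformation). Regenerated by
# scripts/dev/make_standin_dihedrals.py.
seq_number,phi,psi,omega
36,,-47.0000,180.0
37,-57.0000,-47.0000,180.0
38,-57.0000,-47.0000,180.0
39,-57.0000,-47.0000,180.0
40,-57.0000,-47.0000,180.0
41,-57.0000,-47.0000,180.0
42,-165.0000,169.6803,180.0
43,-109.8478,80.0000,180.0
44,-165.0000,180.0000,180.0
45,-157.2152,156.1775,180.0
46,79.9999,80.0000,180.0
47,80.0000,80.0000,180.0
48,-121.5650,161.8794,180.0
49,-155.4520,80.0000,180.0
50,-165.0000,170.5666,180.0
51,-152.1076,80.0000,180.0
52,117.3000,-170.9000,180.0
53,-40.3237,-20.0000,180.0
54,-39.0458,-70.0000,180.0
55,-90.0000,-21.4478,180.0
56,-57.0000,-47.0000,180.0
57,-57.0000,-47.0000,180.0
58,-57.0000,-47.0000,180.0
59,-57.0000,-47.0000,180.0
60,-57.0000,,180.0
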