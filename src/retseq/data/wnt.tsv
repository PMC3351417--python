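# Published fold changes for Wnt-signaling transcripts in the STZ-diabetic mouse retina.
# Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Sfrp1	Secreted frizzled-related protein 1	3.9	2.9	1.9
Wnt7b	Wingless-related MMTV integration site 7B	2.9	1.9	1.5
Wnt7a	Wingless-related MMTV integration site 7A	2.1	1.5	1.5
Mfrp	Membrane-type frizzled-related protein	2.1	1.9	1.5
Cldn1	Claudin 1	1.6	1.4	1.4
Cldn2	Claudin 2	1.6	1.4	1.6
BMP4	Bone morphogenetic protein 4	1.5	1.6	1.5
Id2	Inhibitor of DNA binding 2	1.4	1.6	1.4
Axin1	Axin 1; axis inhibition protein 1	1.3	1.2	1.6
FRAT2	Frequently rearranged in advanced T-cell lymphomas 2	1.2	1.4	1.8
Wnt5b	Wingless-related MMTV integration site 5B	1.2	1.3	1.4
Wisp1	WNT1 inducible signaling pathway protein 1	1.5 (down)	1.6 (down)	2.4 (down)
Wnt2b	Wingless related MMTV integration site 2b	1.1 (down)	1.1 (down)	1.05 (down)
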