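# Published fold changes for inflammatory-pathway transcripts in the STZ-diabetic mouse retina.
# Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
C1qtnf5	C1q and tumor necrosis factor related protein 5	2.2	1.9	1.5
CD44	CD44 antigen	1.7	1.3	1.2
Ltbp1	Latent transforming growth factor beta binding protein 1	1.6	1.4	1.4
Islr	Immunoglobulin superfamily containing leucine-rich repeat	1.6	1.5	1.6
Hspb1	Heat shock protein 1	1.6	1.6	1.2
Ifitm1	Interferon induced transmembrane protein 1	1.5	1.4	1.3
Bmp4	Bone morphogenetic protein 4	1.5	1.6	1.5
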