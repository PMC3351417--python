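# Published fold changes for microvasculature transcripts in the STZ-diabetic mouse retina.
# Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Edn3	Endothelin 3	1.4	1.5	1.4
VEGFB	Vascular endothelial growth factor B	1.1	1.3 (down)	1.1 (down)
VEGFA	Vascular endothelial growth factor A	1.02	1.4	1.3
Edn2	Endothelin 2	1.4 (down)	1.6 (down)	2.0 (down)
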