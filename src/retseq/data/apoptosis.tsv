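# Published fold changes for apoptosis-pathway transcripts in the STZ-diabetic mouse retina.
# Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Dapl1	Death associated protein-like 1	2.6	1.2	1.2
Bid	BH3 interacting domain death agonist	1.6	1.5	1.3
Fads3	Fatty acid desaturase 3	1.3	1.2	1.2
Fas	Fas (TNF receptor superfamily member 6)	1.3	1.1	1.2
Bag5	BCL2-associated athanogene 5	1.2	1.2	1.4
Traf3ip3	TRAF3 interacting protein 3	1.5 (down)	1.5 (down)	2.5 (down)
Tnfsf13	Tumor Necrosis Factor superfamily member 13	1.4 (down)	1.5 (down)	1.6 (down)
Tnfrsf18	Tumor necrosis factor receptor superfamily, member 18	1.4 (down)	1.7 (down)	2.2 (down)
Casp7	Caspase 7	1.4 (down)	1.5 (down)	2.0 (down)
Bcl7c	B-cell CLL/lymphoma 7C	1.1 (down)	1.6 (down)	1.3 (down)
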