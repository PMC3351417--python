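# Published fold changes for neuronal-function transcripts in the STZ-diabetic mouse retina.
# Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Pcgf2	Polycomb group ring finger 2	1.5	1.3	1.2
Slc15a2	Solute carrier family 15 (H+/peptide transporter), member 2	1.3	1.1	1.1
Kcnq4	Potassium voltage-gated channel, subfamily Q, member 4	1.2	1.1	1.1 (down)
Chrna2	Cholinergic receptor, nicotinic, alpha polypeptide 2 (neuronal)	1.2	1.2	1.2
Grinl1a	Glutamate receptor, ionotropic, NMDA like 1A	1.2	2	2
Chrm4	Cholinergic receptor, muscarinic 4	1.04	1.2	1.4
Slc6a5	Solute carrier family 6 (neurotransmitter transporter, glycine), member 5	1	1.39 (down)	1.32 (down)
Kcnip4	Kv channel interacting protein 4	1.25 (down)	1.13 (down)	1.62 (down)
Kcnma1	Potassium large conductance calcium-activated channel, subfamily M, alpha member 1	1.24 (down)	1.62 (down)	1.57 (down)
Grin1	Glutamate receptor, ionotropic, NMDA1 (zeta 1)	1.21 (down)	1.79 (down)	1.47 (down)
Chrnb3	Cholinergic receptor, nicotinic, beta polypeptide 3	1.08 (down)	1.44 (down)	1.35 (down)
Fez1	Fasciculation and elongation protein zeta 1 (zygin I)	1.03 (down)	1.35 (down)	1.29 (down)
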