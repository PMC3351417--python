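# Published fold changes for photoreceptor-specific transcripts in the STZ-diabetic mouse retina.
# Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Cngb3	Cyclic nucleotide gated channel beta 3	1.3 (down)	1.4 (down)	1.4 (down)
Arr3	Arrestin 3, retinal	1.3 (down)	1.6 (down)	1.8 (down)
Gnb3	Guanine nucleotide binding protein (G protein), beta 3	1.3 (down)	1.7 (down)	1.8 (down)
Pde6h	Phosphodiesterase 6H, cGMP-specific, cone, gamma	1.2 (down)	1.8 (down)	2.2 (down)
Pde6a	Phosphodiesterase 6A, cGMP-specific, rod, alpha	1.2 (down)	1.4 (down)	1.5 (down)
Gnat2	Guanine nucleotide binding protein, alpha transducing 2	1.1 (down)	1.3 (down)	1.2 (down)
Crxos1	Crx opposite strand transcript 1	1.1 (down)	1.4 (down)	1.7 (down)
Pde6c	Phosphodiesterase 6C, cGMP specific, cone, alpha prime	1.1 (down)	1.7 (down)	1.8 (down)
Nrl	Neural retina leucine zipper gene	1.02 (down)	1.1	1.1
Crx	Cone-rod homeobox containing gene	1.03	1.3	1.2
Nr2e3	Nuclear receptor subfamily 2, group E, member 3	1.01	1.11 (down)	1.22 (down)
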