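# Published fold changes for crystallin transcripts in the STZ-diabetic mouse retina.
# Contrasts: diabetic vs nondiabetic (D_vs_N), diabetic + RAGE inhibitor vs nondiabetic
# (T1_vs_N), diabetic + p38 MAPK inhibitor vs nondiabetic (T2_vs_N).
# Entries are fold magnitudes; "(down)" marks decreased abundance.
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Crybb2	Crystallin, Beta B2	19.8	3.6	2.4
Cryba1	Crystallin, Beta A1	19.3	3.7	1.9
Cryba4	Crystallin, Beta A4	18.3	3.8	2.4
Crygs	Crystallin, Gamma S	18.2	3.9	2.5
Cryaa	Crystallin, Alpha A	17.9	3.5	2.4
Cryba2	Crystallin, Beta A2	16.4	3.4	2.1
Crybb1	Crystallin, Beta B1	15.1	3.9	2.8
Crybb3	Crystallin, Beta B3	9.2	3.2	2.5
Cryab	Crystallin, Alpha B	6.6	3.6	1.9
Crygb	Crystallin, Gamma B	4.5	3.2	2.2
Crygd	Crystallin, Gamma D	3.9	2.6	2.3
Crygc	Crystallin, Gamma C	2.4	1.7	1.6
Crygn	Crystallin, Gamma N	1.6	1.5	1.2
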