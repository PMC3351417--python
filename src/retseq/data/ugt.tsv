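# Published fold changes for UDP-glucuronosyl transferase transcripts in the STZ-diabetic
# mouse retina. Contrasts: D_vs_N, T1_vs_N (RAGE inhibitor), T2_vs_N (p38 MAPK inhibitor).
gene_symbol	gene_name	D_vs_N	T1_vs_N	T2_vs_N
Ugt1a5	UDP glucuronosyltransferase 1 family, polypeptide A5	3.3	2	1.5
Ugt1a10	UDP glucuronosyltransferase 1 family, polypeptide A10	3.3	2	1.5
Ugt1a1	UDP glucuronosyltransferase 1 family, polypeptide A1	3.3	2	1.5
Ugt1a9	UDP glucuronosyltransferase 1 family, polypeptide A9	3.3	2	1.5
Ugt1a2	UDP glucuronosyltransferase 1 family, polypeptide A2	3.3	2	1.5
Ugt1a7c	UDP glucuronosyltransferase 1 family, polypeptide A7C	3.3	1.9	1.5
Ugt1a6a	UDP glucuronosyltransferase 1 family, polypeptide A6A	3.3	2	1.5
Ugt1a6b	UDP glucuronosyltransferase 1 family, polypeptide A6B	3.1	2.1	1.5
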