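# Ten-locus Alzheimer's risk-score weight table: APOE (via rs429358, the
# epsilon-4-defining SNP) plus the nine top non-APOE loci of the AlzGene
# meta-analysis rankings circa January 2013.  Odds ratios are approximate
# stand-in values for simulation and testing; supply your own weight file
# for real analyses.
locus_id	gene	effect_allele	or	is_apoe
rs429358	APOE	C	3.685	1
rs744373	BIN1	G	1.166	0
rs11136000	CLU	T	0.879	0
rs3764650	ABCA7	G	1.229	0
rs3818361	CR1	A	1.174	0
rs3851179	PICALM	A	0.879	0
rs610932	MS4A6A	T	0.904	0
rs3865444	CD33	A	0.893	0
rs670139	MS4A4E	T	1.079	0
rs9349407	CD2AP	C	1.117	0
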