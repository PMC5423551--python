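rsid	effect_allele	other_allele	eaf	beta	se	or	ci_lower	ci_upper	p	n
rs10741657	C	A				1.02	0.96	1.07	0.56	15008
rs12785878	G	T				0.95	0.90	1.01	0.11	15008
rs2282679	C	A				1.00	0.95	1.06	0.96	15008
rs6013897	A	G				1.03	0.97	1.10	0.38	15008
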