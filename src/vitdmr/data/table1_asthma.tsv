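rsid	effect_allele	other_allele	eaf	beta	se	or	ci_lower	ci_upper	p	n
rs10741657	C	A				0.99	0.97	1.01	0.54	142551
rs12785878	G	T				1.01	0.98	1.03	0.64	142551
rs2282679	C	A				1.01	0.99	1.04	0.31	144243
rs6013897	A	G				1.02	0.99	1.05	0.14	144243
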