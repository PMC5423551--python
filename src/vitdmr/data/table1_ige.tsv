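rsid	effect_allele	other_allele	eaf	beta	se	or	ci_lower	ci_upper	p	n
rs10741657	C	A		-0.02			-0.23	0.19	0.86	12853
rs12785878	G	T		-0.15			-0.36	0.06	0.20	12853
rs2282679	C	A		0.06			-0.17	0.29	0.60	12853
rs6013897	A	G		0.02			-0.25	0.29	0.90	12853
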