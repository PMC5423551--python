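rsid	locus	effect_allele	other_allele	eaf	beta	p	f_stat	variance_explained_pct
rs10741657	CYP2R1	C	A	0.62	-0.052	3.3e-20	18.78	0.13
rs12785878	DHCR7	G	T	0.27	-0.056	2.1e-27	18.29	0.12
rs2282679	GC	C	A	0.3	-0.047	1.9e-109	13.38	0.09
rs6013897	CYP24A1	A	G	0.19	-0.027	6.0e-10	3.13	0.02
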