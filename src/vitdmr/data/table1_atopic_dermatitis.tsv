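rsid	effect_allele	other_allele	eaf	beta	se	or	ci_lower	ci_upper	p	n
rs10741657	C	A				1.02	0.99	1.05	0.27	40834
rs12785878	G	T				1.02	0.98	1.06	0.32	40834
rs2282679	C	A				0.98	0.94	1.02	0.32	40531
rs6013897	A	G				1.03	0.99	1.07	0.22	40529
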