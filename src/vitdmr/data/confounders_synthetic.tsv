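rsid	confounder	p
rs10741657	BMI	0.41
rs12785878	BMI	0.29
rs2282679	BMI	0.63
rs6013897	BMI	0.35
rs10741657	smoking	0.52
rs12785878	smoking	0.18
rs2282679	smoking	0.77
rs6013897	smoking	0.44
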