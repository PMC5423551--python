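rsid_a	rsid_b	r2
rs10741657	rs12785878	0.01
rs10741657	rs2282679	0.01
rs10741657	rs6013897	0.01
rs12785878	rs2282679	0.01
rs12785878	rs6013897	0.01
rs2282679	rs6013897	0.01
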