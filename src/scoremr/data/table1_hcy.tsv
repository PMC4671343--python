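rsid	gene	effect_allele	eaf	beta	se	p
rs12134663	MTHFR	C	0.20	0.10	0.01	2.5e-21
rs1801133	MTHFR	A	0.34	0.16	0.01	4.3e-104
rs2275565	MTR	G	0.79	0.05	0.01	2.0e-10
rs234709	CBS	C	0.55	0.07	0.01	3.9e-24
rs2851391	CBS	T	0.47	0.06	0.01	1.7e-12
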