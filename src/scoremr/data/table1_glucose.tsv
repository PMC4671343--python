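rsid	gene	effect_allele	eaf	beta	se	p
rs12134663	MTHFR	C	0.20	0.002	0.005	0.69
rs1801133	MTHFR	A	0.34	-0.003	0.004	0.46
rs2275565	MTR	G	0.79	-0.001	0.005	0.91
rs234709	CBS	C	0.55	0.003	0.004	0.38
rs2851391	CBS	T	0.47	-0.001	0.004	0.87
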