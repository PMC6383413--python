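PUBMEDID	DISEASE/TRAIT	P-VALUE	MAPPED_GENE	REPORTED GENE(S)
10000001	Multiple sclerosis	1E-9	CD40	CD40
10000002	Multiple sclerosis	2E-9	PLAU - C10orf55	NR
10000003	Crohn's disease	1E-12	NOD2	NOD2
10000004	Multiple sclerosis	3E-6	IL7R	IL7R
10000005	Multiple sclerosis (severity)	4E-11	IL2RA x IL12A	IL2RA, IL12A
10000006	Multiple sclerosis	5E-10	intergenic	NR
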