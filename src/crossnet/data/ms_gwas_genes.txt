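# Illustrative subset of genes repeatedly associated with multiple sclerosis
# in genome-wide association studies (synthetic demo fixture; not the
# complete GWAS-derived list of any single study).
HLA-DRB1
IL2RA
IL7R
CD58
CD40
PLAU
TNFRSF1A
IRF8
CLEC16A
EVI5
STAT3
TYK2
CD86
CXCR5
IL12A
IL12B
CD6
TAGAP
MERTK
ZFP36L1
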