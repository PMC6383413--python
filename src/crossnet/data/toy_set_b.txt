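# toy immune-side seed set (4 genes, shares PLAU with set A)
CD40
TRAF6
IL6
PLAU
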