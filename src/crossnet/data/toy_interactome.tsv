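source	target
F2	F10
F7	F10
F2	FGA
FGA	FGB
F2	PLG
PLAU	PLG
PLAU	PLAUR
CD40	CD40LG
CD40	TRAF6
IL6	TRAF6
IL6	PLAUR
CD40	PLAU
CD40LG	IL6
F10	PLG
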