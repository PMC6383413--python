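# Literature-based core coagulation cascade gene list (illustrative fixture).
# Covers the intrinsic/extrinsic/common pathways, fibrinolysis and the main
# natural anticoagulants, plus receptors that curated coagulation process
# maps carry (PLAUR, CD40). This is a hand-curated open list, NOT any
# proprietary pathway map.
F2
F3
F5
F7
F8
F9
F10
F11
F12
F13A1
F13B
FGA
FGB
FGG
VWF
KLKB1
KNG1
PLAT
PLAU
PLAUR
PLG
SERPINC1
SERPIND1
SERPINE1
SERPINF2
PROC
PROCR
PROS1
THBD
TFPI
A2M
CD40
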