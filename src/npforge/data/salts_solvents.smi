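[Na+]	sodium
[K+]	potassium
[Li+]	lithium
[Ca+2]	calcium
[Mg+2]	magnesium
[Cl-]	chloride
[Br-]	bromide
[I-]	iodide
[F-]	fluoride
[NH4+]	ammonium
O	water
CO	methanol
CCO	ethanol
CC(=O)O	acetic acid
OC(=O)C(F)(F)F	trifluoroacetic acid
CC(=O)[O-]	acetate
[O-]C(=O)C(F)(F)F	trifluoroacetate
Cl	hydrogen chloride
Br	hydrogen bromide
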