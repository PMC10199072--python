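OCC1OC(O)C(O)C(O)C1O	hexopyranose
OC1OCCC(O)C1O	deoxysugar
Oc1ccccc1	phenol
Oc1ccccc1O	catechol
Oc1ccc(O)cc1	hydroquinone
COc1ccccc1O	guaiacol
O=C1CCCO1	gamma-lactone
O=C1CCCCO1	delta-lactone
CC(O)CC(=O)CC(O)C	polyol-ketide
CC(=O)CC(O)CC(=O)O	polyketide-acid
CC(C)=CCCC(C)=CC	isoprenoid-chain
CC1=CCC(C(C)C)CC1	monoterpene-ring
c1ccc2c(c1)cc[nH]2	indole
O=c1ccc2ccccc2o1	coumarin
c1ccoc1	furan
OCC(O)C(O)CO	tetraol-chain
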