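NC(=O)c1ccccc1	benzamide
NS(=O)(=O)c1ccccc1	benzenesulfonamide
c1ccncc1	pyridine
c1cncnc1	pyrimidine
C1CNCCN1	piperazine
C1COCCN1	morpholine
Fc1ccccc1	fluorobenzene
FC(F)(F)c1ccccc1	trifluoromethylbenzene
CC(=O)Nc1ccccc1	acetanilide
c1cnc[nH]1	imidazole
N#Cc1ccccc1	benzonitrile
C1CCNCC1	piperidine
CC(C)(C)C	tert-butyl
COc1ccccc1	anisole
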