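backbone	formula	n_chains	linkages	description
MAG	C3H6O4	1	ester	monoacyl glycerol
DAG	C3H4O5	2	ester,ester	diacyl glycerol
TAG	C3H2O6	3	ester,ester,ester	triacyl glycerol
CL	C9H14O17P2	4	ester,ester,ester,ester	cardiolipin skeleton (bis-phosphatidyl glycerol)
AEG	C3H6O4	2	ester,ether	mixed acyl/ether glycerol
MEG	C3H8O3	1	ether	monoether glycerol
DEG	C3H8O3	2	ether,ether	diether glycerol
Cer	HNO3	2	alkyl,amide	ceramide (sphingoid base + amide-linked chain)
AD	O3	2	alkyl,ester	1,2-alkanediol (diol chain + ester-linked chain)
FA	O	1	amide	fatty amide
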