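headgroup	backbone	formula	n_chains	linkages	adducts
1G	DAG	C9H14O10	2	ester,ester	MH,MNH4,MHCOO
1G	DEG	C9H18O8	2	ether,ether	MH,MNH4,MHCOO
1G	AEG	C9H16O9	2	ester,ether	MH,MNH4,MHCOO
1G	MEG	C9H18O8	1	ether	MH,MNH4,MHCOO
1G	MAG	C9H16O9	1	ester	MH,MNH4,MHCOO
1G	Cer	C6H11NO8	2	alkyl,amide	MH,MNH4,MHCOO
1G	AD	C6H10O8	2	alkyl,ester	MH,MNH4,MHCOO
2G	DAG	C15H24O15	2	ester,ester	MH,MNH4,MHCOO
2G	DEG	C15H28O13	2	ether,ether	MH,MNH4,MHCOO
2G	Cer	C12H21NO13	2	alkyl,amide	MH,MNH4,MHCOO
1G-GA	DAG	C15H22O16	2	ester,ester	MH,MNH4,MHCOO
GAc-G	DAG	C17H26O16	2	ester,ester	MH,MNH4,MHCOO
NAcG-G	DEG	C17H31NO13	2	ether,ether	MH,MNH4,MHCOO
NAcG-P	DEG	C11H22NO11P	2	ether,ether	MH,MmH
PC	DAG	C8H16NO8P	2	ester,ester	MH,MHCOO
PC	DEG	C8H20NO6P	2	ether,ether	MH,MHCOO
PC	MEG	C8H20NO6P	1	ether	MH,MHCOO
PC	AEG	C8H18NO7P	2	ester,ether	MH,MHCOO
PE	DAG	C5H10NO8P	2	ester,ester	MH,MmH
PE	Cer	C2H7N2O6P	2	alkyl,amide	MH,MmH
PG	DAG	C6H11O10P	2	ester,ester	MH,MmH
DGTS	DAG	C10H17NO7	2	ester,ester	MH
DGCC	DAG	C9H15NO7	2	ester,ester	MH
OL	FA	C5H10N2O3	1	amide	MH,MmH
3Me-OL	FA	C8H16N2O3	1	amide	MH,MmH
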