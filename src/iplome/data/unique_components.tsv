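core	family	formula	n_chains	headgroups	adducts	dbe_max	uns_min	uns_max	oh_max	me_max	ext_max	abr_max	rings	chain_min	chain_max
AR	AR	C43H88O3	2	1G,2G	MH,MNH4,MHCOO	0	1	8	2	1	2	1	0	0	0
GDGT	GDGT	C86H172O6	2	1G,2G	MH,MNH4,MHCOO	12	0	2	0	2	0	0	0	0	0
brGDGT	brGDGT	C66H132O6	2	1G	MH,MNH4,MHCOO	0	0	0	0	14	0	0	0	0	0
GDD	GDD	C83H168O4	2	1G,2G	MH,MNH4,MHCOO	12	0	2	0	2	0	0	0	0	0
brGDD	brGDD	C63H128O4	2	1G	MH,MNH4,MHCOO	0	0	0	0	14	0	0	0	0	0
LAD3	LAD	C3H4O5	2	PC,PE	MH,MmH	0	0	0	0	0	0	0	3	18	22
LAD5	LAD	C3H4O5	2	PC,PE	MH,MmH	0	0	0	0	0	0	0	5	18	22
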