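rule_id	level	evidence	target	formula	mz	polarity	tol_ppm
pc_hg_frag	headgroup	fragment	PC	C5H15NO4P		positive	10
pe_hg_nl	headgroup	neutral_loss	PE	C2H8NO4P		positive	10
pg_hg_nl	headgroup	neutral_loss	PG	C3H9O6P		positive	10
1g_hg_nl	headgroup	neutral_loss	1G	C6H10O5		positive	10
2g_hg_nl	headgroup	neutral_loss	2G	C12H20O10		positive	10
1gga_hg_nl	headgroup	neutral_loss	1G-GA	C12H18O11		positive	10
gacg_hg_nl	headgroup	neutral_loss	GAc-G	C14H22O11		positive	10
nacgg_hg_nl	headgroup	neutral_loss	NAcG-G	C14H23NO10		positive	10
nacgp_hg_nl	headgroup	neutral_loss	NAcG-P	C8H14NO8P		positive	10
dgts_hg_frag	headgroup	fragment	DGTS	C7H14NO2		positive	10
dgcc_hg_frag	headgroup	fragment	DGCC	C5H14NO		positive	10
ol_hg_frag	headgroup	fragment	OL	C5H11N2O		positive	10
3meol_hg_frag	headgroup	fragment	3Me-OL	C8H17N2O		positive	10
cer_bb_nl	backbone-linkage	neutral_loss	Cer	H2O		positive	10
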