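headgroup	formula	description
1G	C6H10O5	monoglycosyl (hexose, condensed)
2G	C12H20O10	diglycosyl
1G-GA	C12H18O11	monoglycosyl glycuronic acid
GAc-G	C14H22O11	acetylglycosyl monoglycosyl
NAcG-G	C14H23NO10	N-acetylglycosaminyl glycosyl
NAcG-P	C8H14NO8P	N-acetylglycosaminyl phosphate
PC	C5H12NO3P	phosphocholine
PE	C2H6NO3P	phosphoethanolamine
PG	C3H7O5P	phosphatidylglycerol headgroup (glycerophosphate, condensed)
DGTS	C7H13NO2	diacylglyceryl trimethylhomoserine betaine
DGCC	C6H11NO2	diacylglyceryl carboxyhydroxymethylcholine betaine
OL	C5H10N2O2	ornithine (condensed via amide)
3Me-OL	C8H16N2O2	N,N,N-trimethyl ornithine
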