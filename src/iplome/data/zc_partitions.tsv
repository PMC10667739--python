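class	backbone_formula	note
MAG	C3H8O3	glycerol unit, formal H closure
DAG	C3H8O3	glycerol unit, formal H closure
TAG	C3H8O3	glycerol unit, formal H closure
CL	C9H22O13P2	three glycerols bridged by two phosphodiesters
AEG	C3H8O3	glycerol unit
MEG	C3H8O3	glycerol unit
DEG	C3H8O3	glycerol unit
Cer	C4H10NO2	sphingoid C1-C3 + amide carbon, N and both oxygens; H by formal closure
AD	C2H6O2	diol C1-C2 and both oxygens
FA	O	amide carbonyl oxygen (nitrogen is counted with the amine headgroup)
AR	C3H8O3	glycerol unit
GDGT	C6H16O6	two glycerol units
brGDGT	C6H16O6	two glycerol units
GDD	C3H8O3	glycerol unit
brGDD	C3H8O3	glycerol unit
LAD	C3H8O3	glycerol unit
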